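"""Typed biological networks and labeled drug–disease pair sets.

The repositioning pipeline consumes six *primary* networks of four types:

``DRGN``
    drug–gene interactions (DrugBank-style export),
``DIGN``
    disease–gene associations (CTD/OMIM/DisGeNET-style; three independent
    instances are expected),
``PPIN``
    protein–protein interactions, pre-mapped to gene identifiers
    (IntAct-style),
``GCN``
    gene co-expression links (COXPRESdb-style).

All networks are binary edge sets: any weight column in a source export
(e.g. a co-expression score) is ignored, because edge weights in this
method arise exclusively from path multiplicity during composition.
Undirected gene–gene networks (PPIN/GCN) are stored canonically with
``left_id <= right_id`` and without self-loops.

Files are plain headered TSV edge lists; ``#``-prefixed lines are skipped.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class NetworkFormatError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Input parsed but violates a structural invariant."""


class NetworkRole(str, enum.Enum):
    DRGN = "DRGN"
    DIGN = "DIGN"
    PPIN = "PPIN"
    GCN = "GCN"


#: node namespaces (left, right) implied by each role
ROLE_NAMESPACES: dict[NetworkRole, tuple[str, str]] = {
    NetworkRole.DRGN: ("drug", "gene"),
    NetworkRole.DIGN: ("disease", "gene"),
    NetworkRole.PPIN: ("gene", "gene"),
    NetworkRole.GCN: ("gene", "gene"),
}


class Label(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


def _check_id(node_id: str, where: str) -> str:
    if not node_id or "\t" in node_id:
        raise ValidationError(f"invalid node identifier {node_id!r} in {where}")
    return node_id


@dataclass(frozen=True)
class TypedNetwork:
    """A deduplicated, role-tagged binary network.

    Edges are held as a frozenset of ``(left_id, right_id)`` string pairs.
    For undirected roles (PPIN/GCN) edges are canonical (``left <= right``)
    and self-loops are absent; construct through :meth:`from_edges` to get
    canonicalization and validation.
    """

    role: NetworkRole
    name: str
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def left_namespace(self) -> str:
        return ROLE_NAMESPACES[self.role][0]

    @property
    def right_namespace(self) -> str:
        return ROLE_NAMESPACES[self.role][1]

    @property
    def is_undirected(self) -> bool:
        return self.role in (NetworkRole.PPIN, NetworkRole.GCN)

    @property
    def left_nodes(self) -> frozenset[str]:
        if self.is_undirected:
            return frozenset(n for e in self.edges for n in e)
        return frozenset(e[0] for e in self.edges)

    @property
    def right_nodes(self) -> frozenset[str]:
        if self.is_undirected:
            return frozenset(n for e in self.edges for n in e)
        return frozenset(e[1] for e in self.edges)

    @classmethod
    def from_edges(
        cls,
        role: NetworkRole | str,
        name: str,
        edges: Iterable[tuple[str, str]],
    ) -> "TypedNetwork":
        """Build a network, deduplicating and (for PPIN/GCN) canonicalizing.

        Self-loops in undirected networks are dropped silently; they carry
        no path information for drug→gene→gene→disease composition.
        """
        role = NetworkRole(role)
        undirected = role in (NetworkRole.PPIN, NetworkRole.GCN)
        out: set[tuple[str, str]] = set()
        for left, right in edges:
            _check_id(left, name)
            _check_id(right, name)
            if undirected:
                if left == right:
                    continue
                if right < left:
                    left, right = right, left
            out.add((left, right))
        return cls(role=role, name=name, edges=frozenset(out))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class LabeledPairSet:
    """Drug–disease pairs with positive / negative / unlabeled status."""

    pairs: tuple[tuple[str, str, Label], ...]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, Label | str]]
    ) -> "LabeledPairSet":
        seen: dict[tuple[str, str], Label] = {}
        ordered: list[tuple[str, str, Label]] = []
        for drug, disease, label in pairs:
            label = Label(label)
            key = (drug, disease)
            if key in seen:
                if seen[key] != label:
                    raise ValidationError(
                        f"conflicting labels for pair {key}: "
                        f"{seen[key].value} vs {label.value}"
                    )
                continue
            seen[key] = label
            ordered.append((drug, disease, label))
        return cls(pairs=tuple(ordered))

    def with_label(self, label: Label) -> "LabeledPairSet":
        return LabeledPairSet(
            tuple(p for p in self.pairs if p[2] == label)
        )

    @property
    def positives(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (d, s) for d, s, l in self.pairs if l == Label.POSITIVE
        )

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _, _ in self.pairs)

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(s for _, s, _ in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __add__(self, other: "LabeledPairSet") -> "LabeledPairSet":
        return LabeledPairSet.from_pairs(self.pairs + other.pairs)


def _iter_records(path: Path, header: bool):
    """Yield (line_number, fields) for data lines of a TSV edge list."""
    with open(path, "r", encoding="utf-8") as fh:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            if header and first_data:
                first_data = False
                continue
            first_data = False
            yield lineno, line.split("\t")


def load_network(
    path: str | Path,
    role: NetworkRole | str,
    name: str | None = None,
    header: bool = True,
    id_map: Mapping[str, str] | None = None,
) -> TypedNetwork:
    """Load a primary network from a TSV edge list.

    Parameters
    ----------
    path
        Two-or-more-column TSV; columns beyond the second (e.g. scores)
        are ignored.
    role
        One of DRGN/DIGN/PPIN/GCN; fixes the node namespaces.
    name
        Network label (defaults to the file stem).
    header
        Whether the first non-comment line is a header.
    id_map
        Optional identifier renaming applied to *gene-namespace* columns,
        e.g. protein accession → gene symbol for a PPIN export. Identifiers
        absent from the map are kept as-is.

    Raises
    ------
    NetworkFormatError
        On a line with fewer than two fields or an empty identifier,
        naming the line number.
    """
    path = Path(path)
    role = NetworkRole(role)
    name = name if name is not None else path.stem
    left_ns, right_ns = ROLE_NAMESPACES[role]

    def rename(node: str, namespace: str) -> str:
        if id_map is not None and namespace == "gene":
            return id_map.get(node, node)
        return node

    edges: list[tuple[str, str]] = []
    n_lines = 0
    for lineno, fields in _iter_records(path, header):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise NetworkFormatError(
                f"{path}: line {lineno}: expected >=2 tab-separated "
                f"non-empty fields, got {fields!r}"
            )
        n_lines += 1
        edges.append(
            (rename(fields[0], left_ns), rename(fields[1], right_ns))
        )
    net = TypedNetwork.from_edges(role, name, edges)
    logger.info(
        "loaded %s network %r: %d %s nodes, %d %s nodes, %d edges "
        "(%d raw lines)",
        role.value, name, len(net.left_nodes), left_ns,
        len(net.right_nodes), right_ns, len(net), n_lines,
    )
    return net


def load_labeled_pairs(
    path: str | Path,
    positive_token: str = "approved",
    negative_token: str = "terminated",
    header: bool = True,
) -> LabeledPairSet:
    """Load labeled drug–disease pairs.

    Two-field lines are positives (benchmark files that list known
    associations only); three-field lines carry a status token mapped to
    positive / negative, with unknown tokens kept as unlabeled.
    """
    path = Path(path)
    records: list[tuple[str, str, Label]] = []
    for lineno, fields in _iter_records(path, header):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise NetworkFormatError(
                f"{path}: line {lineno}: expected drug<TAB>disease"
                f"[<TAB>status], got {fields!r}"
            )
        if len(fields) == 2 or not fields[2]:
            label = Label.POSITIVE
        elif fields[2] == positive_token:
            label = Label.POSITIVE
        elif fields[2] == negative_token:
            label = Label.NEGATIVE
        else:
            try:  # canonical tokens, so our own output round-trips
                label = Label(fields[2])
            except ValueError:
                label = Label.UNLABELED
        records.append((fields[0], fields[1], label))
    pairs = LabeledPairSet.from_pairs(records)
    logger.info(
        "loaded %d labeled pairs from %s (%d positive, %d negative)",
        len(pairs), path,
        sum(1 for p in pairs.pairs if p[2] == Label.POSITIVE),
        sum(1 for p in pairs.pairs if p[2] == Label.NEGATIVE),
    )
    return pairs


def write_network(net, path: str | Path) -> None:
    """Write a TypedNetwork or ComposedNetwork as headered TSV.

    Rows are sorted for byte-reproducible output; composed networks get an
    integer weight column. The output round-trips losslessly through
    :func:`load_network` / ``composition.load_composed``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            if hasattr(net, "weights"):  # ComposedNetwork
                fh.write("drug_id\tdisease_id\tweight\n")
                for (drug, disease), w in sorted(net.weights.items()):
                    fh.write(f"{drug}\t{disease}\t{w}\n")
            else:
                left, right = ROLE_NAMESPACES[net.role]
                fh.write(f"{left}_id\t{right}_id\n")
                for a, b in sorted(net.edges):
                    fh.write(f"{a}\t{b}\n")
    except OSError as exc:
        raise OSError(f"cannot write network to {path}: {exc}") from exc


def write_labeled_pairs(pairs: LabeledPairSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\tstatus\n")
        for drug, disease, label in pairs.pairs:
            fh.write(f"{drug}\t{disease}\t{label.value}\n")


def load_id_map(path: str | Path, header: bool = True) -> dict[str, str]:
    """Load a two-column old-id → new-id mapping table (TSV)."""
    out: dict[str, str] = {}
    for lineno, fields in _iter_records(Path(path), header):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise NetworkFormatError(
                f"{path}: line {lineno}: expected old_id<TAB>new_id"
            )
        out[fields[0]] = fields[1]
    return out
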