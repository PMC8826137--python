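"""Input/output and validation for chronograms, geography tables and epoch models.

Three plain-text dialects are canonical here:

* **Newick** chronograms (read/written through dendropy), required to be
  rooted, binary and ultrametric — branch lengths in millions of years,
  node ages measured backward from the present (present = 0 Ma).
* **Lagrange/PHYLIP geography**: first line ``<ntaxa> <nareas> (<codes...>)``,
  then one line per taxon, ``<name> <0/1 string>``.
* **Epoch multipliers**: one block per time slice, youngest slice first and
  oldest last; each block is a header ``<old_age>-<young_age>``, then
  ``nareas`` rows of ``nareas`` numbers, then a line ``END``.

Event logs (one row per anagenetic or cladogenetic event of a sampled or
simulated history) are tab-separated tables read and written with pandas.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Chronogram",
    "GeographyTable",
    "EpochModel",
    "GeoIOError",
    "read_chronogram",
    "write_chronogram",
    "read_geography",
    "write_geography",
    "read_multipliers",
    "write_multipliers",
    "read_event_log",
    "write_event_log",
    "EVENT_LOG_COLUMNS",
]

ULTRAMETRIC_TOL = 1e-6  # Ma

EVENT_LOG_COLUMNS = [
    "replicate",
    "branch_id",
    "age_Ma",
    "event_type",
    "range_before",
    "range_after",
]


class GeoIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Chronogram
# ---------------------------------------------------------------------------


class Chronogram:
    """Rooted, binary, ultrametric time-calibrated tree.

    Internally an array representation: nodes ``0 .. n_nodes-1`` with tips
    first (``0 .. n_tips-1``), ``parent[root] == -1``, ages in Ma before
    present (tips at 0), and ``children`` mapping each internal node to its
    (left, right) daughters.
    """

    def __init__(self, parent, ages, labels, children):
        self.parent = np.asarray(parent, dtype=int)
        self.ages = np.asarray(ages, dtype=float)
        self.labels = list(labels)
        self.children = {int(k): (int(v[0]), int(v[1])) for k, v in children.items()}
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise GeoIOError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.postorder = self._postorder()
        self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> "Chronogram":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf() and len(nd.child_nodes()) != 2:
                raise GeoIOError("tree must be strictly bifurcating")
        # depths from root
        depth = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                depth[nd] = 0.0
            else:
                bl = nd.edge.length
                if bl is None:
                    raise GeoIOError("all branches must have lengths")
                depth[nd] = depth[nd.parent_node] + float(bl)
        max_depth = max(depth[lf] for lf in leaves)
        for lf in leaves:
            if abs(depth[lf] - max_depth) > tol:
                raise GeoIOError(
                    f"tree is not ultrametric: tip {lf.taxon.label!r} deviates by "
                    f"{abs(depth[lf] - max_depth):.3g} Ma (tolerance {tol:g})"
                )
        labels = []
        index = {}
        for i, lf in enumerate(leaves):
            if lf.taxon is None or not lf.taxon.label:
                raise GeoIOError("every tip must be labelled")
            labels.append(lf.taxon.label)
            index[lf] = i
        n_tips = len(labels)
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for j, nd in enumerate(internals):
            index[nd] = n_tips + j
        n_nodes = n_tips + len(internals)
        parent = np.full(n_nodes, -1, dtype=int)
        ages = np.zeros(n_nodes)
        children = {}
        for nd in tree.preorder_node_iter():
            i = index[nd]
            # tips snapped to the present (auto-extension within tolerance)
            ages[i] = 0.0 if nd.is_leaf() else max_depth - depth[nd]
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
            if not nd.is_leaf():
                l, r = nd.child_nodes()
                children[i] = (index[l], index[r])
        return cls(parent, ages, labels, children)

    @classmethod
    def from_newick(cls, newick: str, tol: float = ULTRAMETRIC_TOL) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:
            raise GeoIOError(f"cannot parse Newick: {exc}") from exc
        return cls.from_dendropy(tree, tol=tol)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for v in range(self.n_nodes):
            nd = dendropy.Node()
            if v < self.n_tips:
                nd.taxon = taxa.new_taxon(label=self.labels[v])
            nodes[v] = nd
        for v, (l, r) in self.children.items():
            nodes[v].add_child(nodes[l])
            nodes[v].add_child(nodes[r])
        for v in range(self.n_nodes):
            p = self.parent[v]
            nodes[v].edge.length = None if p < 0 else float(self.ages[p] - self.ages[v])
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True  # otherwise dendropy derooting collapses the root
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    # -- queries ------------------------------------------------------------

    def _postorder(self):
        order, stack, seen = [], [self.root], []
        while stack:
            v = stack.pop()
            seen.append(v)
            if v in self.children:
                stack.extend(self.children[v])
        for v in reversed(seen):
            order.append(v)
        return order

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return float(self.ages[p] - self.ages[v]) if p >= 0 else 0.0

    @property
    def total_length(self) -> float:
        return float(sum(self.branch_length(v) for v in range(self.n_nodes) if v != self.root))

    def tip_index(self, label: str) -> int:
        return self.labels.index(label)

    def clade_tips(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return out

    def mrca(self, tip_labels) -> int:
        want = set(tip_labels)
        missing = want - set(self.labels)
        if missing:
            raise GeoIOError(f"unknown tips: {sorted(missing)}")
        for v in self.postorder:
            got = {self.labels[t] for t in self.clade_tips(v)}
            if want <= got:
                return v
        return self.root

    def drop_tips(self, labels) -> "Chronogram":
        """Prune the named tips (e.g. outgroups), suppressing unifurcations."""
        labels = list(labels)
        missing = set(labels) - set(self.labels)
        if missing:
            raise GeoIOError(f"cannot drop unknown tips: {sorted(missing)}")
        tree = self.to_dendropy()
        taxa = [t for t in tree.taxon_namespace if t.label in set(labels)]
        tree.prune_taxa(taxa)
        tree.purge_taxon_namespace()
        return Chronogram.from_dendropy(tree)

    def validate(self, tol: float = ULTRAMETRIC_TOL) -> None:
        if len(set(self.labels)) != self.n_tips:
            raise GeoIOError("tip labels must be unique")
        if np.any(np.abs(self.ages[: self.n_tips]) > tol):
            raise GeoIOError("tips must sit at the present (age 0)")
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and not self.ages[p] - self.ages[v] > 0:
                raise GeoIOError(
                    f"non-positive branch length above node {v} "
                    f"(parent age {self.ages[p]:.6g}, child age {self.ages[v]:.6g})"
                )

    def __repr__(self):
        return f"<Chronogram: {self.n_tips} tips, root age {self.root_age:.4g} Ma>"


def read_chronogram(path, tol: float = ULTRAMETRIC_TOL) -> Chronogram:
    with open(path) as fh:
        return Chronogram.from_newick(fh.read(), tol=tol)


def write_chronogram(tree: Chronogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# GeographyTable
# ---------------------------------------------------------------------------


@dataclass
class GeographyTable:
    """Taxon-by-area presence table over an ordered list of area codes.

    ``presence`` maps each taxon to a bitmask: bit ``i`` set means the taxon
    occurs in ``areas[i]``. Area order is fixed by the file header and is the
    single ordering all downstream state indices derive from.
    """

    areas: list[str]
    presence: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.areas)) != len(self.areas):
            raise GeoIOError("area codes must be unique")
        for taxon, mask in self.presence.items():
            if mask <= 0:
                raise GeoIOError(f"empty range for taxon {taxon!r}")
            if mask >= 1 << len(self.areas):
                raise GeoIOError(f"range of {taxon!r} uses undefined areas")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def taxa(self) -> list[str]:
        return list(self.presence)

    def range_set(self, taxon: str) -> frozenset:
        mask = self.presence[taxon]
        return frozenset(self.areas[i] for i in range(self.n_areas) if mask >> i & 1)

    def range_str(self, taxon: str) -> str:
        return "".join(self.areas[i] for i in range(self.n_areas) if self.presence[taxon] >> i & 1)

    def check_against(self, tree: Chronogram) -> None:
        tips, taxa = set(tree.labels), set(self.presence)
        if tips != taxa:
            extra, missing = sorted(taxa - tips), sorted(tips - taxa)
            raise GeoIOError(f"geography/tree mismatch: extra={extra}, missing={missing}")

    def subset(self, taxa) -> "GeographyTable":
        return GeographyTable(list(self.areas), {t: self.presence[t] for t in taxa})

    def to_dataframe(self) -> pd.DataFrame:
        rows = {
            t: [self.presence[t] >> i & 1 for i in range(self.n_areas)] for t in self.presence
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.areas)


def read_geography(path_or_buf) -> GeographyTable:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise GeoIOError("empty geography file")
    head = lines[0].replace("(", " ").replace(")", " ").split()
    if len(head) < 2:
        raise GeoIOError("line 1: expected '<ntaxa> <nareas> (<codes...>)'")
    try:
        ntaxa, nareas = int(head[0]), int(head[1])
    except ValueError as exc:
        raise GeoIOError(f"line 1: bad counts: {exc}") from None
    codes = head[2:]
    if not codes:
        codes = [chr(ord("A") + i) for i in range(nareas)]
    if len(codes) != nareas:
        raise GeoIOError(f"line 1: {nareas} areas declared but {len(codes)} codes given")
    if len(lines) - 1 != ntaxa:
        raise GeoIOError(f"{ntaxa} taxa declared but {len(lines) - 1} rows found")
    presence: dict[str, int] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != 2:
            raise GeoIOError(f"line {lineno}: expected '<taxon> <bits>'")
        taxon, bits = parts
        if taxon in presence:
            raise GeoIOError(f"line {lineno}: duplicate taxon {taxon!r}")
        if len(bits) != nareas or set(bits) - {"0", "1"}:
            raise GeoIOError(f"line {lineno}: bad bit string {bits!r} (need {nareas} of 0/1)")
        mask = sum(1 << i for i, b in enumerate(bits) if b == "1")
        if mask == 0:
            raise GeoIOError(f"line {lineno}: empty range for taxon {taxon!r}")
        presence[taxon] = mask
    return GeographyTable(codes, presence)


def write_geography(table: GeographyTable, path) -> None:
    buf = _io.StringIO()
    buf.write(f"{len(table.presence)} {table.n_areas} ({' '.join(table.areas)})\n")
    for taxon, mask in table.presence.items():
        bits = "".join("1" if mask >> i & 1 else "0" for i in range(table.n_areas))
        buf.write(f"{taxon} {bits}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# EpochModel
# ---------------------------------------------------------------------------


@dataclass
class EpochModel:
    """Time slices with per-slice dispersal multiplier matrices.

    ``boundaries`` are slice edges in Ma before present, strictly descending
    and ending at 0 (e.g. ``[11, 7, 0]`` for slices 11–7 and 7–0 Ma);
    ``multipliers[i]`` is the area×area matrix for the *i*-th slice counted
    from the oldest. ``multipliers[i][a, b]`` scales the base dispersal rate
    from area ``a`` into area ``b`` within that slice; diagonals are 1 by
    convention and entries are nonnegative.
    """

    boundaries: np.ndarray
    multipliers: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        b = self.boundaries
        if b.ndim != 1 or len(b) < 2 or b[-1] != 0 or np.any(np.diff(b) >= 0):
            raise GeoIOError("boundaries must strictly descend to 0 (e.g. [11, 7, 0])")
        if self.multipliers.ndim != 3 or self.multipliers.shape[0] != len(b) - 1:
            raise GeoIOError("need one square multiplier matrix per slice")
        if self.multipliers.shape[1] != self.multipliers.shape[2]:
            raise GeoIOError("multiplier matrices must be square")
        if np.any(self.multipliers < 0):
            raise GeoIOError("multiplier entries must be nonnegative")
        for i in range(self.n_slices):
            np.fill_diagonal(self.multipliers[i], 1.0)

    @property
    def n_slices(self) -> int:
        return len(self.boundaries) - 1

    @property
    def n_areas(self) -> int:
        return self.multipliers.shape[1]

    @classmethod
    def uniform(cls, n_areas: int, oldest: float = np.inf) -> "EpochModel":
        """Single slice of all-ones multipliers — the unconstrained model."""
        return cls(np.array([oldest, 0.0]), np.ones((1, n_areas, n_areas)))

    def slice_index(self, age: float) -> int:
        """Slice containing the given age; ages at a boundary go to the younger slice."""
        if age < 0:
            raise GeoIOError(f"negative age {age}")
        for i in range(self.n_slices - 1, -1, -1):
            if age <= self.boundaries[i]:
                return i
        raise GeoIOError(
            f"age {age:g} Ma is older than the oldest slice boundary "
            f"{self.boundaries[0]:g} Ma"
        )

    def segments(self, young_age: float, old_age: float):
        """Split [young_age, old_age] at slice boundaries.

        Returns a list of ``(duration, slice_index)`` ordered from the young
        end toward the old end — the order in which tip-side partial
        likelihoods are propagated rootward.
        """
        if old_age < young_age:
            raise GeoIOError("ages out of order")
        cuts = [young_age]
        for b in self.boundaries[-2::-1]:  # interior boundaries, ascending
            if young_age < b < old_age:
                cuts.append(float(b))
        cuts.append(old_age)
        segs = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            if hi > lo:
                segs.append((hi - lo, self.slice_index(0.5 * (lo + hi))))
        return segs


def read_multipliers(path_or_buf) -> EpochModel:
    if hasattr(path_or_buf, "read"):
        raw = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            raw = fh.read().splitlines()
    lines = [ln.strip() for ln in raw if ln.strip()]
    blocks = []  # (old, young, matrix)
    i = 0
    while i < len(lines):
        header = lines[i]
        try:
            old_s, young_s = header.split("-")
            old, young = float(old_s), float(young_s)
        except ValueError:
            raise GeoIOError(f"bad slice header {header!r}: expected '<old>-<young>'") from None
        i += 1
        rows = []
        while i < len(lines) and lines[i] != "END":
            try:
                rows.append([float(x) for x in lines[i].split()])
            except ValueError:
                raise GeoIOError(f"bad matrix row {lines[i]!r}") from None
            i += 1
        if i == len(lines):
            raise GeoIOError(f"slice {header!r}: missing END")
        i += 1  # consume END
        n = len(rows)
        if n == 0 or any(len(r) != n for r in rows):
            raise GeoIOError(f"slice {header!r}: matrix must be square")
        if old <= young:
            raise GeoIOError(f"slice {header!r}: old age must exceed young age")
        blocks.append((old, young, np.array(rows)))
    if not blocks:
        raise GeoIOError("no slice blocks found")
    blocks.sort(key=lambda b: -b[0])  # oldest first internally
    for (old_a, young_a, _), (old_b, young_b, _) in zip(blocks[:-1], blocks[1:]):
        if young_a != old_b:
            raise GeoIOError(
                f"slices are not contiguous: {old_a}-{young_a} then {old_b}-{young_b}"
            )
    if blocks[-1][1] != 0:
        raise GeoIOError("youngest slice must reach the present (young age 0)")
    boundaries = [blocks[0][0]] + [b[1] for b in blocks]
    return EpochModel(np.array(boundaries), np.stack([b[2] for b in blocks]))


def write_multipliers(model: EpochModel, path) -> None:
    with open(path, "w") as fh:
        # youngest block first, oldest last (matching the read convention)
        for i in range(model.n_slices - 1, -1, -1):
            old, young = model.boundaries[i], model.boundaries[i + 1]
            fh.write(f"{old:g}-{young:g}\n")
            for row in model.multipliers[i]:
                fh.write(" ".join(f"{x:g}" for x in row) + "\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# Event logs
# ---------------------------------------------------------------------------


def write_event_log(df: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise GeoIOError(f"event log missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False)


def read_event_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
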