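"""Composite head/hinge alignment, distances, and neighbor-joining trees.

SMC proteins share three alignable anchors — the N- and C-terminal
halves of the ATPase head and the central hinge. Members are aligned to
a reference, the three regions are cut out, re-aligned separately and
concatenated into one composite matrix; columns with more than 30% gaps
are removed before tree inference. Distances are Poisson-corrected
p-distances (d = -ln(1 - p), p clamped at 0.95 to stay finite) and the
tree is neighbor joining with column-resampling bootstrap supports. The
trimmed composite can be exported (relaxed PHYLIP + partition file) for
external maximum-likelihood programs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._align import GAP, X_INDEX, encode, global_align
from ._nj import NJNode, nj_tree
from .cluster_align import progressive_align
from .errors import ValidationError
from .seq_io import Alignment, write_fasta

REGION_ORDER = ("headN", "headC", "hinge")
DEFAULT_MAX_GAP = 0.30
DEFAULT_MIN_IDENTITY = 0.20
DEFAULT_MIN_OVERLAP = 50
MAX_P_DISTANCE = 0.95
DEFAULT_BOOTSTRAP_REPS = 100


@dataclass
class RegionSpec:
    """Head-N / head-C / hinge spans on a reference sequence (0-based,
    half-open)."""

    reference_name: str
    reference_seq: str
    spans: dict  # region -> (start, end)

    def __post_init__(self) -> None:
        self.reference_seq = self.reference_seq.upper()
        if set(self.spans) != set(REGION_ORDER):
            raise ValidationError(f"RegionSpec: spans must cover {REGION_ORDER}")
        L = len(self.reference_seq)
        ivs = []
        for region in REGION_ORDER:
            s, e = self.spans[region]
            if not (0 <= s < e <= L):
                raise ValidationError(f"RegionSpec: span {region} outside the reference")
            if e - s < 10:
                raise ValidationError(f"RegionSpec: span {region} shorter than 10 columns")
            ivs.append((s, e))
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError("RegionSpec: spans overlap")


@dataclass
class CompositeAlignment:
    """Concatenated region alignments with block boundaries and per-column
    gap fractions."""

    alignment: Alignment
    block_boundaries: list  # (region, start, end), half-open columns
    column_gap_fraction: np.ndarray = field(default=None)
    excluded: dict = field(default_factory=dict)  # member -> reason

    def __post_init__(self) -> None:
        if self.column_gap_fraction is None:
            self.column_gap_fraction = gap_fractions(self.alignment)
        total = sum(e - s for _, s, e in self.block_boundaries)
        if total != self.alignment.n_cols:
            raise ValidationError("CompositeAlignment: blocks do not partition columns")


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValidationError("DistanceMatrix: shape mismatch")
        if np.abs(self.matrix - self.matrix.T).max(initial=0.0) > 1e-12:
            raise ValidationError("DistanceMatrix: not symmetric")
        if np.any(np.diag(self.matrix) != 0.0):
            raise ValidationError("DistanceMatrix: nonzero diagonal")
        if np.any(self.matrix < 0.0):
            raise ValidationError("DistanceMatrix: negative distances")


def gap_fractions(aln: Alignment) -> np.ndarray:
    if aln.n_rows == 0:
        return np.zeros(0)
    arr = np.array([list(r) for r in aln.rows])
    return (arr == GAP).mean(axis=0)


def _member_ref_columns(member: str, reference: str, min_identity: float, name: str):
    score, gm, gr = global_align(member, reference)
    matches = sum(
        1 for a, b in zip(gm, gr) if a == b and a != GAP and a != "X"
    )
    identity = matches / min(len(member), len(reference))
    if identity < min_identity:
        raise ValidationError(
            f"extract_region: member {name or '<unnamed>'} aligns at identity "
            f"{identity:.2f} < {min_identity:.2f} to the reference"
        )
    return gm, gr


def _fragment_from_alignment(gm: str, gr: str, span: tuple[int, int]) -> str:
    s, e = span
    frag = []
    ref_pos = 0
    inside = False
    for cm, cr in zip(gm, gr):
        if cr != GAP:
            inside = s <= ref_pos < e
            ref_pos += 1
        # insertion columns (cr == GAP) inherit `inside` from the last
        # reference position, so insertions within the span are kept and
        # flanking insertions are not
        if inside and cm != GAP:
            frag.append(cm)
        if cr != GAP and ref_pos >= e:
            inside = s <= ref_pos < e  # closes the span after its last column
    return "".join(frag)


def extract_region(
    member: str,
    spec: RegionSpec,
    region: str,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    name: str = "",
) -> str:
    """Member residues that align within the reference span of one region."""
    if region not in REGION_ORDER:
        raise ValidationError(f"extract_region: unknown region {region!r}")
    gm, gr = _member_ref_columns(member.upper(), spec.reference_seq, min_identity, name)
    return _fragment_from_alignment(gm, gr, spec.spans[region])


def build_composite(
    members: dict[str, str],
    spec: RegionSpec,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    per_block_pretrim: bool = False,
    max_gap: float = DEFAULT_MAX_GAP,
) -> CompositeAlignment:
    """Extract all three regions per member, re-align each region, and
    concatenate in headN, headC, hinge order.

    Members that fail the identity floor are excluded with a warning and
    recorded on the returned object.
    """
    if len(members) < 4:
        raise ValidationError("build_composite: need at least 4 members")
    fragments: dict[str, dict[str, str]] = {r: {} for r in REGION_ORDER}
    excluded: dict[str, str] = {}
    for name in sorted(members):
        try:
            gm, gr = _member_ref_columns(
                members[name].upper(), spec.reference_seq, min_identity, name
            )
        except ValidationError as exc:
            excluded[name] = str(exc)
            warnings.warn(f"build_composite: excluding {name}: {exc}")
            continue
        for region in REGION_ORDER:
            fragments[region][name] = _fragment_from_alignment(gm, gr, spec.spans[region])

    kept = sorted(set(members) - set(excluded))
    if len(kept) < 2:
        raise ValidationError("build_composite: fewer than 2 members survived extraction")

    blocks: list[Alignment] = []
    for region in REGION_ORDER:
        aln = progressive_align([(n, fragments[region][n]) for n in kept])
        if per_block_pretrim:
            keep = gap_fractions(aln) <= max_gap
            if not keep.any():
                raise ValidationError(
                    f"build_composite: pre-trim removed every column of {region}"
                )
            aln = Alignment(
                names=aln.names,
                rows=["".join(np.array(list(r))[keep]) for r in aln.rows],
            )
        blocks.append(aln)

    boundaries = []
    offset = 0
    rows = {n: "" for n in kept}
    for region, aln in zip(REGION_ORDER, blocks):
        for n, row in zip(aln.names, aln.rows):
            rows[n] += row
        boundaries.append((region, offset, offset + aln.n_cols))
        offset += aln.n_cols
    composite = Alignment(names=kept, rows=[rows[n] for n in kept])
    return CompositeAlignment(
        alignment=composite, block_boundaries=boundaries, excluded=excluded
    )


def trim_gappy_columns(
    caln: CompositeAlignment, max_gap: float = DEFAULT_MAX_GAP
) -> CompositeAlignment:
    """Retain exactly the columns with gap fraction <= max_gap; idempotent."""
    keep = caln.column_gap_fraction <= max_gap
    if not keep.any():
        raise ValidationError("trim_gappy_columns: every column exceeds the gap cutoff")
    arr = np.array([list(r) for r in caln.alignment.rows])
    rows = ["".join(r) for r in arr[:, keep]]
    kept_before = np.concatenate(([0], np.cumsum(keep)))
    boundaries = [
        (region, int(kept_before[s]), int(kept_before[e]))
        for region, s, e in caln.block_boundaries
    ]
    return CompositeAlignment(
        alignment=Alignment(names=list(caln.alignment.names), rows=rows),
        block_boundaries=boundaries,
        excluded=dict(caln.excluded),
    )


def _as_alignment(aln) -> Alignment:
    return aln.alignment if isinstance(aln, CompositeAlignment) else aln


def distance_matrix(
    aln,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_p: float = MAX_P_DISTANCE,
) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) over mutually non-gap
    columns; X never matches; p is clamped at max_p."""
    a = _as_alignment(aln)
    if a.n_rows < 2:
        raise ValidationError("distance_matrix: need at least 2 rows")
    codes = np.array([encode(r.replace(GAP, "X")) for r in a.rows])
    nongap = np.array([[c != GAP for c in r] for r in a.rows])
    n = a.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mutual = nongap[i] & nongap[j]
            m = int(mutual.sum())
            if m < min_overlap:
                raise ValidationError(
                    f"distance_matrix: rows {a.names[i]!r} and {a.names[j]!r} share "
                    f"only {m} non-gap columns (need {min_overlap})"
                )
            ci, cj = codes[i][mutual], codes[j][mutual]
            diff = (ci != cj) | (ci == X_INDEX) | (cj == X_INDEX)
            p = min(float(diff.mean()), max_p)
            D[i, j] = D[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(names=list(a.names), matrix=D)


def _nj_node_to_dendropy(root: NJNode, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(node: NJNode, parent) -> None:
        for child, bl in node.children:
            dnode = parent.new_child(edge_length=float(bl))
            if child.name is not None and not child.children:
                dnode.taxon = tns.require_taxon(label=child.name)
            else:
                build(child, dnode)

    build(root, tree.seed_node)
    tree.is_rooted = False
    return tree


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic tie-breaks, branch
    lengths clamped at zero, unrooted output."""
    root = nj_tree(list(D.names), D.matrix)
    tns = dendropy.TaxonNamespace()
    return _nj_node_to_dendropy(root, tns)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as frozensets of the side not holding the
    smallest taxon label."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(below) <= len(leaves) - 2:
            splits.add(leaves - below if anchor in below else below)
    return splits


def bootstrap_support(
    aln,
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports (% of column-resampled replicates
    containing each internal split of the point-estimate tree)."""
    if reps < 1:
        raise ValidationError("bootstrap_support: reps must be >= 1")
    a = _as_alignment(aln)
    point = neighbor_joining(distance_matrix(a, min_overlap=min_overlap))
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in a.rows])
    counts: dict[frozenset, int] = {s: 0 for s in tree_bipartitions(point)}
    for _ in range(reps):
        cols = rng.integers(0, a.n_cols, size=a.n_cols)
        rep_aln = Alignment(
            names=list(a.names), rows=["".join(r) for r in arr[:, cols]]
        )
        try:
            rep_tree = neighbor_joining(distance_matrix(rep_aln, min_overlap=1))
        except ValidationError:
            continue  # replicate contributes no splits
        rep_splits = tree_bipartitions(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    leaves = frozenset(l.taxon.label for l in point.leaf_node_iter())
    anchor = min(leaves)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        key = leaves - below if anchor in below else below
        if key in counts:
            node.label = f"{100.0 * counts[key] / reps:.0f}"
    return point


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            )
        )


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)


def export_for_ml(caln: CompositeAlignment, out_prefix: str) -> dict[str, str]:
    """Write relaxed PHYLIP, aligned FASTA and a partition file delimiting
    the three blocks (for external maximum-likelihood inference)."""
    a = caln.alignment
    paths = {
        "phylip": f"{out_prefix}.phy",
        "fasta": f"{out_prefix}.fasta",
        "partitions": f"{out_prefix}.partitions",
    }
    with open(paths["phylip"], "w") as fh:
        fh.write(f"{a.n_rows} {a.n_cols}\n")
        for name, row in zip(a.names, a.rows):
            fh.write(f"{name}  {row}\n")
    write_fasta(zip(a.names, a.rows), paths["fasta"])
    with open(paths["partitions"], "w") as fh:
        for region, s, e in caln.block_boundaries:
            if e > s:
                fh.write(f"PROT, {region} = {s + 1}-{e}\n")
    return paths
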