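"""Greedy identity clustering and progressive multiple alignment.

Clustering reduces redundancy before profile building (the field default
for this step is an 80% identity cutoff). The progressive aligner builds
a guide tree by neighbor joining on 3-mer cosine distances and merges
profiles by dynamic programming with sum-of-pairs BLOSUM62 column
scores. Identity uses min-length as the denominator, so fragments
compare against the region they cover.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import GAP, N_SYMBOLS, affine_dp, blosum62, encode
from ._nj import NJNode, nj_tree
from .errors import ValidationError
from .seq_io import Alignment

DEFAULT_IDENTITY_THRESHOLD = 0.80
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass
class Cluster:
    representative: str
    members: list[str]
    identity_threshold: float


def pairwise_identity(
    a: str,
    b: str,
    *,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Fraction of identically aligned residues over min(len a, len b).

    The pair is canonicalized (lexicographic order) before aligning so
    the result is exactly symmetric even when co-optimal alignments
    exist. X never counts as an identity.
    """
    if not a or not b:
        raise ValidationError("pairwise_identity: empty sequence")
    x, y = sorted((a.upper(), b.upper()))
    sub = blosum62()
    S = sub[encode(x)[:, None], encode(y)[None, :]]
    r = affine_dp(S, gap_open, gap_extend, traceback=True)
    matches = sum(
        1
        for i, j in zip(r.a_cols, r.b_cols)
        if i is not None and j is not None and x[i] == y[j] and x[i] != "X"
    )
    return matches / min(len(a), len(b))


def cluster_sequences(
    seqs: list[tuple[str, str]],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[Cluster]:
    """Greedy incremental clustering, longest sequence first (ties by name).

    Each sequence joins the first existing cluster whose representative
    it matches at >= threshold identity, else founds a new cluster.
    """
    names = [n for n, _ in seqs]
    if len(set(names)) != len(names):
        raise ValidationError("cluster_sequences: duplicate sequence names")
    by_name = dict(seqs)
    order = sorted(names, key=lambda n: (-len(by_name[n]), n))
    clusters: list[Cluster] = []
    for name in order:
        seq = by_name[name]
        placed = False
        for cl in clusters:
            if pairwise_identity(by_name[cl.representative], seq) >= threshold:
                cl.members.append(name)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=name, members=[name], identity_threshold=threshold)
            )
    return clusters


def write_clusters_tsv(clusters: list[Cluster], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tmember\tidentity_threshold\n")
        for cl in clusters:
            for member in sorted(cl.members):
                fh.write(f"{cl.representative}\t{member}\t{cl.identity_threshold}\n")


def _column_frequencies(rows: list[str]) -> np.ndarray:
    """(n_cols x 21) residue frequencies; gaps contribute no mass."""
    n_rows = len(rows)
    n_cols = len(rows[0]) if rows else 0
    F = np.zeros((n_cols, N_SYMBOLS))
    for row in rows:
        codes = encode(row.replace(GAP, "?"))  # '?' -> X, fixed below
        is_gap = np.fromiter((c == GAP for c in row), dtype=bool, count=n_cols)
        cols = np.nonzero(~is_gap)[0]
        np.add.at(F, (cols, codes[cols]), 1.0)
    return F / n_rows


def _merge(a: Alignment, b: Alignment, sub, gap_open: float, gap_extend: float) -> Alignment:
    FA = _column_frequencies(a.rows)
    FB = _column_frequencies(b.rows)
    S = FA @ sub @ FB.T
    r = affine_dp(S, gap_open, gap_extend, traceback=True)
    rows_a = ["" for _ in a.rows]
    rows_b = ["" for _ in b.rows]
    for ca, cb in zip(r.a_cols, r.b_cols):
        for k, row in enumerate(a.rows):
            rows_a[k] += row[ca] if ca is not None else GAP
        for k, row in enumerate(b.rows):
            rows_b[k] += row[cb] if cb is not None else GAP
    return Alignment(names=a.names + b.names, rows=rows_a + rows_b)


def _kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    k = max(1, min(k, min(len(s) for s in seqs)))
    vocab: dict[str, int] = {}
    vecs = []
    for s in seqs:
        counts: dict[int, float] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            idx = vocab.setdefault(kmer, len(vocab))
            counts[idx] = counts.get(idx, 0.0) + 1.0
        vecs.append(counts)
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = vecs[i], vecs[j]
            dot = sum(v * vj.get(key, 0.0) for key, v in vi.items())
            ni = np.sqrt(sum(v * v for v in vi.values()))
            nj = np.sqrt(sum(v * v for v in vj.values()))
            cos = dot / (ni * nj) if ni > 0 and nj > 0 else 0.0
            D[i, j] = D[j, i] = 1.0 - cos
    return D


def _align_guide(node: NJNode, leaf_alignments: dict[str, Alignment], sub, go, ge) -> Alignment:
    if node.name is not None and not node.children:
        return leaf_alignments[node.name]
    merged: Alignment | None = None
    for child, _bl in node.children:
        sub_aln = _align_guide(child, leaf_alignments, sub, go, ge)
        merged = sub_aln if merged is None else _merge(merged, sub_aln, sub, go, ge)
    return merged


def progressive_align(
    seqs: list[tuple[str, str]],
    *,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Progressive MSA: NJ guide tree on 3-mer cosine distances, then
    profile-profile merges with sum-of-pairs BLOSUM62 scores.

    Input order does not matter: sequences are canonicalized by name
    before the guide tree is built. Degapping any output row returns its
    input sequence unchanged.
    """
    if not seqs:
        raise ValidationError("progressive_align: need at least one sequence")
    names = [n for n, _ in seqs]
    if len(set(names)) != len(names):
        raise ValidationError("progressive_align: duplicate sequence names")
    ordered = sorted(seqs, key=lambda p: p[0])
    sub = blosum62()
    leaf = {n: Alignment(names=[n], rows=[s.upper()]) for n, s in ordered}

    if len(ordered) == 1:
        aln = leaf[ordered[0][0]]
    elif len(ordered) == 2:
        aln = _merge(leaf[ordered[0][0]], leaf[ordered[1][0]], sub, gap_open, gap_extend)
    else:
        D = _kmer_distance_matrix([s for _, s in ordered])
        root = nj_tree([n for n, _ in ordered], D)
        aln = _align_guide(root, leaf, sub, gap_open, gap_extend)

    order = {n: i for i, n in enumerate(aln.names)}
    keep = sorted(aln.names)
    return Alignment(names=keep, rows=[aln.rows[order[n]] for n in keep])
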