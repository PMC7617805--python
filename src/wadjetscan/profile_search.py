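"""Per-family position-specific scoring matrices and proteome searches.

A profile is built from a family alignment: columns with more than 50%
gaps are insert columns and excluded; each match column scores residue a
as log2(((c_a + alpha*b_a) / (N + alpha)) / b_a) bits, with uniform
background by default. Sequences are scored by local (Smith-Waterman)
alignment of the profile's match columns to the protein with affine gap
penalties in bits; unknown residues (X) score zero everywhere.

Bit-score thresholds replace E-values: on desk-scale databases the
Karlin-Altschul calibration buys nothing, and the threshold is exposed
as configuration per family.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._align import ALPHABET, X_INDEX, affine_dp, encode
from .errors import ValidationError
from .seq_io import Alignment, GenomeSet

FAMILIES = ("MksB", "MksE", "MksF", "MksG")
DEFAULT_BIT_THRESHOLD = 50.0
DEFAULT_GAP_OPEN_BITS = 11.0
DEFAULT_GAP_EXTEND_BITS = 1.0
DEFAULT_MAX_COLUMN_GAP = 0.50
PROFILE_SCHEMA_VERSION = 1


@dataclass
class Profile:
    """Log-odds scoring matrix (bits) for one protein family."""

    family: str
    match_scores: np.ndarray  # (n_match x 21); column 20 is X and scores 0
    background: np.ndarray  # probability vector over the 20 amino acids
    gap_open: float = DEFAULT_GAP_OPEN_BITS
    gap_extend: float = DEFAULT_GAP_EXTEND_BITS
    source_alignment_hash: str = ""

    def __post_init__(self) -> None:
        self.match_scores = np.asarray(self.match_scores, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 21:
            raise ValidationError("profile: match_scores must be (n_match x 21)")
        if self.match_scores.shape[0] < 1:
            raise ValidationError("profile: needs at least one match column")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValidationError("profile: background must sum to 1")
        if not np.isfinite(self.match_scores).all():
            raise ValidationError("profile: non-finite scores")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("profile: gap penalties must be positive")

    @property
    def n_match(self) -> int:
        return int(self.match_scores.shape[0])

    def consensus_score(self) -> float:
        return float(self.match_scores[:, :20].max(axis=1).sum())

    def to_dict(self) -> dict:
        return {
            "schema_version": PROFILE_SCHEMA_VERSION,
            "family": self.family,
            "alphabet": ALPHABET,
            "columns": self.match_scores[:, :20].tolist(),
            "background": self.background.tolist(),
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "source_alignment_hash": self.source_alignment_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Profile":
        if d.get("schema_version") != PROFILE_SCHEMA_VERSION:
            raise ValidationError(
                f"profile JSON schema version {d.get('schema_version')} not supported"
            )
        cols = np.asarray(d["columns"], dtype=np.float64)
        scores = np.zeros((cols.shape[0], 21))
        scores[:, :20] = cols
        return cls(
            family=d["family"],
            match_scores=scores,
            background=np.asarray(d["background"], dtype=np.float64),
            gap_open=float(d["gap_open"]),
            gap_extend=float(d["gap_extend"]),
            source_alignment_hash=d.get("source_alignment_hash", ""),
        )


@dataclass
class Hit:
    """Best local match of one protein against one family profile."""

    gene_id: str
    family: str
    bit_score: float
    query_span: tuple[int, int]  # 0-based half-open residue interval
    above_threshold: bool = False


def alignment_hash(aln: Alignment) -> str:
    h = hashlib.sha256()
    for name, row in zip(aln.names, aln.rows):
        h.update(name.encode())
        h.update(b"\x00")
        h.update(row.encode())
        h.update(b"\x01")
    return h.hexdigest()


def build_profile(
    aln: Alignment,
    family: str,
    *,
    alpha: float = 1.0,
    background: np.ndarray | None = None,
    max_column_gap: float = DEFAULT_MAX_COLUMN_GAP,
    gap_open: float = DEFAULT_GAP_OPEN_BITS,
    gap_extend: float = DEFAULT_GAP_EXTEND_BITS,
) -> Profile:
    """Build a PSSM from a family alignment.

    alpha is the pseudocount weight; columns whose gap fraction exceeds
    max_column_gap become insert columns and are dropped from the model.
    """
    if aln.n_rows == 0:
        raise ValidationError("build_profile: empty alignment")
    if alpha <= 0:
        raise ValidationError("build_profile: alpha must be positive")
    bg = (
        np.full(20, 1.0 / 20.0)
        if background is None
        else np.asarray(background, dtype=np.float64)
    )
    n_rows = aln.n_rows
    columns = []
    for j in range(aln.n_cols):
        col = [row[j] for row in aln.rows]
        gap_fraction = col.count("-") / n_rows
        if gap_fraction > max_column_gap:
            continue
        counts = np.zeros(20)
        for c in col:
            if c == "-" or c == "X":
                continue
            idx = encode(c)[0]
            if idx != X_INDEX:
                counts[idx] += 1.0
        n_col = counts.sum()
        probs = (counts + alpha * bg) / (n_col + alpha)
        scores = np.zeros(21)
        scores[:20] = np.log2(probs / bg)
        columns.append(scores)
    if not columns:
        raise ValidationError("build_profile: alignment has zero match columns")
    return Profile(
        family=family,
        match_scores=np.vstack(columns),
        background=bg,
        gap_open=gap_open,
        gap_extend=gap_extend,
        source_alignment_hash=alignment_hash(aln),
    )


def _profile_cell_scores(profile: Profile, protein: str) -> np.ndarray:
    codes = encode(protein)
    # rows: protein residues; cols: profile match columns
    return profile.match_scores[:, codes].T


def local_profile_score(profile: Profile, protein: str) -> float:
    """Score-only local alignment (used for fast proteome screening)."""
    if not protein:
        raise ValidationError("local_profile_score: empty protein")
    S = _profile_cell_scores(profile, protein)
    return affine_dp(S, profile.gap_open, profile.gap_extend, local=True).score


def score_sequence(
    profile: Profile,
    protein: str,
    *,
    gene_id: str = "",
    threshold: float = DEFAULT_BIT_THRESHOLD,
) -> Hit:
    """Best local profile-to-sequence alignment; bit score is never negative."""
    if not protein:
        raise ValidationError("score_sequence: empty protein")
    S = _profile_cell_scores(profile, protein)
    r = affine_dp(S, profile.gap_open, profile.gap_extend, local=True, traceback=True)
    span = r.span_a()
    return Hit(
        gene_id=gene_id,
        family=profile.family,
        bit_score=r.score,
        query_span=span,
        above_threshold=r.score >= threshold,
    )


def search_proteome(
    profiles: dict[str, Profile],
    genomes: GenomeSet,
    threshold: float = DEFAULT_BIT_THRESHOLD,
) -> dict[str, Hit]:
    """Assign every gene its single best family; return above-threshold hits.

    Ties in bit score break on lexicographic family name.
    """
    if not profiles:
        raise ValidationError("search_proteome: need at least one profile")
    hits: dict[str, Hit] = {}
    fams = sorted(profiles)
    for contig in genomes.contigs:
        for gene in contig.genes:
            best_fam, best_score = None, -1.0
            for fam in fams:
                s = local_profile_score(profiles[fam], gene.protein)
                if s > best_score:
                    best_fam, best_score = fam, s
            if best_fam is not None and best_score >= threshold:
                hits[gene.gene_id] = score_sequence(
                    profiles[best_fam],
                    gene.protein,
                    gene_id=gene.gene_id,
                    threshold=threshold,
                )
    return hits


def write_profiles_json(profiles: dict[str, Profile], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {fam: profiles[fam].to_dict() for fam in sorted(profiles)},
            fh,
            indent=1,
            sort_keys=True,
        )


def read_profiles_json(path: str) -> dict[str, Profile]:
    with open(path) as fh:
        data = json.load(fh)
    return {fam: Profile.from_dict(d) for fam, d in data.items()}
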