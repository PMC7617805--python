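"""Candidate operon calling and the filter cascade with auditable reasons.

A candidate is three co-directional genes whose profile hits, taken in
gene order, are a permutation of {MksF, MksE, MksB}; a co-directional
MksG hit immediately up- or downstream is attached (upstream preferred).
Filters: MksB must be longer than 890 residues (strictly) and carry a
Walker-A motif; MksF must be 400-1200 residues and MksE 150-800
(inclusive ranges); the whole operon must sit at least two genes away
from both contig ends so only fully sequenced operons survive.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .errors import ValidationError
from .profile_search import Hit
from .seq_io import ContigAnnotation, GenomeSet

CORE_FAMILIES = ("MksF", "MksE", "MksB")
FAMILY_LETTER = {"MksF": "F", "MksE": "E", "MksB": "B"}

REASON_B_LEN = "B_LEN"
REASON_B_WALKER = "B_WALKER"
REASON_F_LEN = "F_LEN"
REASON_E_LEN = "E_LEN"
REASON_EDGE = "EDGE"
REASON_CODES = (REASON_B_LEN, REASON_B_WALKER, REASON_F_LEN, REASON_E_LEN, REASON_EDGE)

B_MIN_LEN = 890  # strictly "larger than"
F_RANGE = (400, 1200)  # inclusive
E_RANGE = (150, 800)  # inclusive
EDGE_MARGIN = 2

WALKER_A = re.compile(r"[AG].{4}GK[ST]")
WALKER_B = re.compile(r"[ILVFM]{4}D[ED]")


@dataclass
class OperonCall:
    """One candidate/accepted operon with its filter audit."""

    assembly_id: str
    contig_id: str
    core: dict  # family -> order_index
    mksg: int | None
    strand: str
    order_signature: str
    accepted: bool = True
    reasons: tuple = ()
    core_gene_ids: tuple = ()  # ((family, gene_id), ...)
    mksg_gene_id: str | None = None

    @property
    def member_indices(self) -> list[int]:
        idx = sorted(self.core.values())
        if self.mksg is not None:
            idx = sorted(idx + [self.mksg])
        return idx

    @property
    def first_index(self) -> int:
        return self.member_indices[0]

    @property
    def last_index(self) -> int:
        return self.member_indices[-1]


def walker_a_present(protein: str) -> bool:
    """True iff the Walker-A P-loop pattern [AG]xxxxGK[ST] occurs anywhere."""
    if not protein:
        raise ValidationError("walker_a_present: empty protein")
    return WALKER_A.search(protein.upper()) is not None


def walker_b_present(protein: str) -> bool:
    if not protein:
        raise ValidationError("walker_b_present: empty protein")
    return WALKER_B.search(protein.upper()) is not None


def find_candidate_operons(
    contig: ContigAnnotation,
    hits: dict[str, Hit],
    *,
    assembly_id: str = "",
    attach_mksg: bool = True,
    g_codirectional: bool = True,
    window_slack: int = 0,
) -> list[OperonCall]:
    """Scan one contig for unfiltered candidate operons.

    Consecutive means the three core hits are the next three family hits
    along the contig and span at most 2 + window_slack gene positions
    (slack 0 = strictly adjacent). Overlaps resolve left-to-right
    greedily. Only above-threshold hits may be passed in.
    """
    genes = contig.genes
    fam_at = {}
    for g in genes:
        h = hits.get(g.gene_id)
        if h is not None:
            if not h.above_threshold:
                raise ValidationError(
                    f"find_candidate_operons: below-threshold hit for {g.gene_id}"
                )
            fam_at[g.order_index] = h.family
    core_idx = sorted(i for i, f in fam_at.items() if f in CORE_FAMILIES)

    calls: list[OperonCall] = []
    used_until = -1
    t = 0
    while t + 2 < len(core_idx):
        i, j, k = core_idx[t], core_idx[t + 1], core_idx[t + 2]
        fams = (fam_at[i], fam_at[j], fam_at[k])
        strands = {genes[i].strand, genes[j].strand, genes[k].strand}
        if (
            i > used_until
            and k - i <= 2 + window_slack
            and set(fams) == set(CORE_FAMILIES)
            and len(strands) == 1
        ):
            strand = genes[i].strand
            mksg = None
            if attach_mksg:
                up, down = i - 1, k + 1
                for cand in (up, down):  # upstream preferred
                    if 0 <= cand < contig.n_genes and fam_at.get(cand) == "MksG":
                        if g_codirectional and genes[cand].strand != strand:
                            continue
                        mksg = cand
                        break
            core = {fams[0]: i, fams[1]: j, fams[2]: k}
            calls.append(
                OperonCall(
                    assembly_id=assembly_id,
                    contig_id=contig.contig_id,
                    core=core,
                    mksg=mksg,
                    strand=strand,
                    order_signature="".join(FAMILY_LETTER[f] for f in fams),
                    core_gene_ids=tuple(
                        (f, genes[core[f]].gene_id) for f in CORE_FAMILIES
                    ),
                    mksg_gene_id=None if mksg is None else genes[mksg].gene_id,
                )
            )
            used_until = max(k, mksg if mksg is not None else k)
            while t < len(core_idx) and core_idx[t] <= used_until:
                t += 1
        else:
            t += 1
    return calls


def apply_length_and_motif_filters(
    call: OperonCall,
    contig: ContigAnnotation,
    *,
    b_min_len: int = B_MIN_LEN,
    f_range: tuple[int, int] = F_RANGE,
    e_range: tuple[int, int] = E_RANGE,
    use_walker_b: bool = False,
) -> OperonCall:
    """Append B_LEN / B_WALKER / F_LEN / E_LEN reasons as violated."""
    b = contig.genes[call.core["MksB"]].protein
    f = contig.genes[call.core["MksF"]].protein
    e = contig.genes[call.core["MksE"]].protein
    reasons = list(call.reasons)
    if len(b) <= b_min_len:
        reasons.append(REASON_B_LEN)
    has_walker = walker_a_present(b) or (use_walker_b and walker_b_present(b))
    if not has_walker:
        reasons.append(REASON_B_WALKER)
    if not (f_range[0] <= len(f) <= f_range[1]):
        reasons.append(REASON_F_LEN)
    if not (e_range[0] <= len(e) <= e_range[1]):
        reasons.append(REASON_E_LEN)
    return replace(call, reasons=tuple(reasons), accepted=not reasons)


def contig_edge_filter(
    call: OperonCall,
    contig: ContigAnnotation,
    *,
    margin: int = EDGE_MARGIN,
) -> OperonCall:
    """Append EDGE unless >= margin genes flank the operon on both sides."""
    first, last = call.first_index, call.last_index
    n = contig.n_genes
    reasons = list(call.reasons)
    if not (first >= margin and (n - 1 - last) >= margin):
        reasons.append(REASON_EDGE)
    return replace(call, reasons=tuple(reasons), accepted=not reasons)


def infer_operons(
    genomes: GenomeSet,
    hits: dict[str, Hit],
    *,
    attach_mksg: bool = True,
    g_codirectional: bool = True,
    window_slack: int = 0,
    b_min_len: int = B_MIN_LEN,
    f_range: tuple[int, int] = F_RANGE,
    e_range: tuple[int, int] = E_RANGE,
    use_walker_b: bool = False,
    edge_margin: int = EDGE_MARGIN,
    apply_edge_filter: bool = True,
) -> list[OperonCall]:
    """Scan every contig; return all calls (accepted or not) with full audit."""
    calls: list[OperonCall] = []
    for contig in genomes.contigs:
        for call in find_candidate_operons(
            contig,
            hits,
            assembly_id=genomes.assembly_id,
            attach_mksg=attach_mksg,
            g_codirectional=g_codirectional,
            window_slack=window_slack,
        ):
            call = apply_length_and_motif_filters(
                call,
                contig,
                b_min_len=b_min_len,
                f_range=f_range,
                e_range=e_range,
                use_walker_b=use_walker_b,
            )
            if apply_edge_filter:
                call = contig_edge_filter(call, contig, margin=edge_margin)
            calls.append(call)
    return calls
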