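"""Synthetic genomes with implanted Mks operons and a truth table.

Families diverge along a known tree under a Poisson/uniform substitution
model (per branch of length b, each site substitutes with probability
1 - exp(-b), the replacement uniform over the other 19 residues). Forged
contigs carry co-directional F-E-B core operons (optionally with a
flanking G) surrounded by random background genes; each distractor
contig violates exactly one acceptance rule, so the truth table maps
1:1 onto the filter vocabulary.

Every MksB implant gets a Walker-A exemplar stitched in at a fixed
offset (except the B_NO_WALKER case, where any motif occurrence is
ablated by a K->R substitution), so motif presence is controlled by the
case code and not left to chance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._align import ALPHABET
from .errors import ValidationError
from .operon_inference import (
    REASON_B_LEN,
    REASON_B_WALKER,
    REASON_E_LEN,
    REASON_EDGE,
    REASON_F_LEN,
    WALKER_A,
)
from .seq_io import ContigAnnotation, GeneRecord, GenomeSet

CASE_CODES = (
    "VALID",
    "VALID_WITH_G",
    "B_TOO_SHORT",
    "B_NO_WALKER",
    "F_OUT_OF_RANGE",
    "E_OUT_OF_RANGE",
    "NOT_CODIRECTIONAL",
    "NOT_CONSECUTIVE",
    "NEAR_CONTIG_EDGE",
    "DECOY_BACKGROUND",
)
ACCEPTING_CASES = ("VALID", "VALID_WITH_G")
EXPECTED_REASON = {
    "B_TOO_SHORT": REASON_B_LEN,
    "B_NO_WALKER": REASON_B_WALKER,
    "F_OUT_OF_RANGE": REASON_F_LEN,
    "E_OUT_OF_RANGE": REASON_E_LEN,
    "NEAR_CONTIG_EDGE": REASON_EDGE,
}

DEFAULT_FAMILY_LENGTHS = {"MksB": 1450, "MksF": 500, "MksE": 230, "MksG": 350}
WALKER_EXEMPLAR = "GASGSGKT"
WALKER_OFFSET = 30
B_TRUNCATED_LEN = 880  # <= 890, so only the length clause trips
F_SHORT_LEN = 350  # < 400
E_SHORT_LEN = 120  # < 150
BACKGROUND_LEN_RANGE = (100, 600)


@dataclass
class EvolutionSpec:
    """Family divergence along a known tree (branch lengths in E[subs/site])."""

    root_length: int
    tree: str  # newick
    seed: int

    def __post_init__(self) -> None:
        if self.root_length <= 0:
            raise ValidationError("EvolutionSpec: root_length must be positive")


@dataclass
class ForgeSpec:
    """Plan for one synthetic genome: one case code per contig."""

    n_contigs: int = len(CASE_CODES)
    genes_per_contig: int = 9
    family_lengths: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_LENGTHS))
    distractor_plan: tuple = CASE_CODES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_contig < 5:
            raise ValidationError("ForgeSpec: genes_per_contig must be >= 5")
        bad = [c for c in self.distractor_plan if c not in CASE_CODES]
        if bad:
            raise ValidationError(f"ForgeSpec: unknown case codes {bad}")
        if self.n_contigs < len(self.distractor_plan):
            raise ValidationError("ForgeSpec: n_contigs smaller than the plan")

    def full_plan(self) -> tuple:
        """The plan padded with DECOY_BACKGROUND up to n_contigs."""
        pad = self.n_contigs - len(self.distractor_plan)
        return tuple(self.distractor_plan) + ("DECOY_BACKGROUND",) * pad


@dataclass
class TruthRow:
    contig_id: str
    gene_indices: tuple
    case_code: str
    expected_accept: bool
    expected_reason: str | None


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


def _mutate(codes: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    if branch_length < 0:
        raise ValidationError("evolve_family: negative branch length")
    p_sub = 1.0 - np.exp(-branch_length)
    mask = rng.random(codes.size) < p_sub
    out = codes.copy()
    if mask.any():
        offsets = rng.integers(1, 20, size=int(mask.sum()))
        out[mask] = (out[mask] + offsets) % 20
    return out


def evolve_family(spec: EvolutionSpec) -> dict[str, str]:
    """Evolve a root protein along the tree; returns leaf_name -> protein."""
    tree = dendropy.Tree.get(data=spec.tree, schema="newick", preserve_underscores=True)
    rng = np.random.default_rng(spec.seed)
    root_codes = rng.integers(0, 20, size=spec.root_length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_codes}
    leaves: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            codes = root_codes
        else:
            parent = seqs[id(node.parent_node)]
            codes = _mutate(parent, node.edge.length or 0.0, rng)
        seqs[id(node)] = codes
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label is None:
                raise ValidationError("evolve_family: unnamed leaf in tree")
            leaves[label] = "".join(ALPHABET[c] for c in codes)
    return leaves


def stitch_walker(protein: str, offset: int = WALKER_OFFSET) -> str:
    motif = WALKER_EXEMPLAR
    if len(protein) < offset + len(motif):
        raise ValidationError("stitch_walker: protein too short for the motif offset")
    return protein[:offset] + motif + protein[offset + len(motif) :]


def ablate_walker(protein: str) -> str:
    """Break every Walker-A occurrence by substituting its invariant K with R."""
    s = protein
    while True:
        m = WALKER_A.search(s)
        if m is None:
            return s
        s = s[: m.start() + 6] + "R" + s[m.start() + 7 :]


def random_join_tree(
    names: list[str],
    rng: np.random.Generator,
    bl_range: tuple[float, float] = (0.05, 0.15),
) -> str:
    """Random binary tree over names as newick, branch lengths uniform."""
    nodes = [f"{n}" for n in names]

    def bl() -> float:
        return float(rng.uniform(*bl_range))

    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a}:{bl():.6f},{b}:{bl():.6f})")
    return nodes[0] + ";"


def make_family_pools(
    family_lengths: dict | None = None,
    n_members: int = 12,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Evolve one pool of diverged members per family along random trees."""
    lengths = dict(DEFAULT_FAMILY_LENGTHS if family_lengths is None else family_lengths)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * len(lengths)) % (2**31)
    pools: dict[str, dict[str, str]] = {}
    for k, fam in enumerate(sorted(lengths)):
        rng = np.random.default_rng(int(child_seeds[2 * k]))
        names = [f"{fam}_m{i:02d}" for i in range(n_members)]
        newick = random_join_tree(names, rng)
        pools[fam] = evolve_family(
            EvolutionSpec(
                root_length=lengths[fam], tree=newick, seed=int(child_seeds[2 * k + 1])
            )
        )
    return pools


def _case_layout(case: str) -> tuple[list[tuple[str, str]], int]:
    """(ordered (slot, strand) implant list, start index) for one case."""
    feb = [("MksF", "+"), ("MksE", "+"), ("MksB", "+")]
    if case in ("VALID", "B_TOO_SHORT", "B_NO_WALKER", "F_OUT_OF_RANGE", "E_OUT_OF_RANGE"):
        return feb, 2
    if case == "VALID_WITH_G":
        return [("MksG", "+")] + feb, 2
    if case == "NOT_CODIRECTIONAL":
        return [("MksF", "+"), ("MksE", "-"), ("MksB", "+")], 2
    if case == "NOT_CONSECUTIVE":
        return [("MksF", "+"), ("bg", "+"), ("MksE", "+"), ("MksB", "+")], 2
    if case == "NEAR_CONTIG_EDGE":
        return feb, 1
    return [], 0  # DECOY_BACKGROUND


def forge_genomes(
    spec: ForgeSpec,
    families: dict[str, dict[str, str]],
) -> tuple[GenomeSet, list[TruthRow]]:
    """Implant one case per contig; returns the genome and its truth table."""
    plan = spec.full_plan()
    rng = np.random.default_rng(spec.seed)
    pools = {fam: [families[fam][n] for n in sorted(families[fam])] for fam in families}
    cursors = {fam: 0 for fam in pools}

    needed: dict[str, int] = {}
    for case in plan:
        for slot, _ in _case_layout(case)[0]:
            if slot != "bg":
                needed[slot] = needed.get(slot, 0) + 1
    for fam, count in needed.items():
        if fam not in pools or len(pools[fam]) < count:
            raise ValidationError(
                f"forge_genomes: family pool for {fam} too small "
                f"(need {count}, have {len(pools.get(fam, []))})"
            )

    def take(fam: str) -> str:
        seq = pools[fam][cursors[fam]]
        cursors[fam] += 1
        return seq

    def background() -> str:
        lo, hi = BACKGROUND_LEN_RANGE
        return _random_protein(rng, int(rng.integers(lo, hi + 1)))

    contigs: list[ContigAnnotation] = []
    truth: list[TruthRow] = []
    for k, case in enumerate(plan):
        contig_id = f"ctg{k:03d}_{case}"
        implants, start = _case_layout(case)
        n = spec.genes_per_contig
        if start + len(implants) + 1 > n:
            raise ValidationError(
                f"forge_genomes: genes_per_contig={n} too small for case {case}"
            )
        slots: list[tuple[str, str]] = [("bg", "+")] * n
        for off, (slot, strand) in enumerate(implants):
            slots[start + off] = (slot, strand)

        genes: list[GeneRecord] = []
        member_indices: list[int] = []
        for idx, (slot, strand) in enumerate(slots):
            if slot == "bg":
                protein = background()
            else:
                protein = take(slot)
                if slot == "MksB":
                    if case == "B_NO_WALKER":
                        protein = ablate_walker(protein)
                    elif case == "B_TOO_SHORT":
                        protein = stitch_walker(protein[:B_TRUNCATED_LEN])
                    else:
                        protein = stitch_walker(protein)
                elif slot == "MksF" and case == "F_OUT_OF_RANGE":
                    protein = protein[:F_SHORT_LEN]
                elif slot == "MksE" and case == "E_OUT_OF_RANGE":
                    protein = protein[:E_SHORT_LEN]
                member_indices.append(idx)
            genes.append(
                GeneRecord(
                    gene_id=f"{contig_id}_g{idx:02d}",
                    contig_id=contig_id,
                    order_index=idx,
                    strand=strand,
                    protein=protein,
                )
            )
        contigs.append(ContigAnnotation(contig_id=contig_id, genes=genes))
        truth.append(
            TruthRow(
                contig_id=contig_id,
                gene_indices=tuple(member_indices),
                case_code=case,
                expected_accept=case in ACCEPTING_CASES,
                expected_reason=EXPECTED_REASON.get(case),
            )
        )
    genome = GenomeSet(assembly_id="synthetic_assembly", contigs=contigs)
    return genome, truth


def write_truth_table(truth: list[TruthRow], path: str) -> None:
    rows = [
        {
            "contig_id": t.contig_id,
            "gene_indices": ",".join(str(i) for i in t.gene_indices),
            "case_code": t.case_code,
            "expected_accept": int(t.expected_accept),
            "expected_reason": t.expected_reason or "",
        }
        for t in truth
    ]
    pd.DataFrame(
        rows,
        columns=["contig_id", "gene_indices", "case_code", "expected_accept", "expected_reason"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> list[TruthRow]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        idx = tuple(int(i) for i in str(r["gene_indices"]).split(",") if i != "")
        out.append(
            TruthRow(
                contig_id=str(r["contig_id"]),
                gene_indices=idx,
                case_code=str(r["case_code"]),
                expected_accept=bool(int(r["expected_accept"])),
                expected_reason=str(r["expected_reason"]) or None,
            )
        )
    return out
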