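"""NG86 Ka/Ks estimation for homologous coding-sequence pairs.

The Nei-Gojobori (1986) counting method: every sense codon is decomposed
into synonymous and nonsynonymous *sites* by enumerating its nine
single-nucleotide mutants against the standard genetic code (changes to
stop codons count as nonsynonymous); observed differences between two
aligned codons are resolved by averaging over all minimal mutational
pathways with equal weight, excluding pathways that pass through a stop
codon. Proportions pN, pS are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3), which is undefined for
p >= 3/4.

Ka/Ks > 1 is read as positive selection, < 1 as purifying, = 1 as
neutral; the ratio is NA when Ks = 0 or a correction is undefined.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {}
for _c in itertools.product(NUCLEOTIDES, repeat=3):
    _codon = "".join(_c)
    _CODON_TABLE[_codon] = "*" if _codon in STOP_CODONS else str(Seq(_codon).translate())

SENSE_CODONS = tuple(c for c in _CODON_TABLE if c not in STOP_CODONS)


def translate_codon(codon: str) -> str:
    try:
        return _CODON_TABLE[codon.upper()]
    except KeyError:
        raise ValueError(f"ambiguous or invalid codon {codon!r}") from None


# ------------------------------------------------------------------ sites


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts (N, S) of a sense codon.

    Per position the synonymous fraction is the share of the three
    possible nucleotide changes that preserve the encoded amino acid;
    N = 3 - S. Raises on stop or ambiguous codons.
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if _CODON_TABLE[mutant] == aa:  # change to stop is nonsynonymous
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (nonsynonymous, synonymous) difference counts between two
    codons over all minimal mutational pathways, equal weights.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all pathways are used (the classic fallback for the rare
    stop-locked case).
    """
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_positions):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_TABLE[nxt] == "*" and len(steps) + 1 < len(diff_positions):
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        nd = sum(1 for a, b in steps if _CODON_TABLE[a] != _CODON_TABLE[b])
        sd = len(steps) - nd
        pathways.append((through_stop, nd, sd))
    valid = [p for p in pathways if not p[0]]
    if not valid:
        valid = pathways
    nd = sum(p[1] for p in valid) / len(valid)
    sd = sum(p[2] for p in valid) / len(valid)
    return nd, sd


# ------------------------------------------------------------- alignment


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-aligned CDS pair; `retained` indexes codon columns without gaps."""

    aligned_a: str
    aligned_b: str
    retained: tuple[int, ...]

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned CDS lengths differ")
        if len(self.aligned_a) % 3:
            raise ValueError("aligned length not divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a) // 3

    def codon_pairs(self):
        for col in self.retained:
            yield self.aligned_a[3 * col: 3 * col + 3], self.aligned_b[3 * col: 3 * col + 3]


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _check_translation(name: str, cds: str, protein: str) -> str:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    codons = [cds[i: i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]  # trim terminal stop
    aas = []
    for i, codon in enumerate(codons):
        aa = translate_codon(codon)
        if aa == "*":
            raise ValueError(f"{name}: internal stop codon at codon {i + 1}")
        aas.append(aa)
    translated = "".join(aas)
    if translated != protein.upper().rstrip("*"):
        raise ValueError(f"{name}: CDS does not translate to the given protein")
    return "".join(codons)


def align_codons(protein_a: str, protein_b: str, cds_a: str, cds_b: str,
                 name_a: str = "seqA", name_b: str = "seqB") -> CodonAlignment:
    """Protein-guided codon alignment.

    The proteins are globally aligned (BLOSUM62, affine gaps open 10 /
    extend 0.5) and the alignment is back-translated codon-wise; codon
    columns containing a gap in either sequence are masked out of
    `retained`.
    """
    cds_a = _check_translation(name_a, cds_a, protein_a)
    cds_b = _check_translation(name_b, cds_b, protein_b)
    alignment = _protein_aligner().align(protein_a.upper().rstrip("*"),
                                         protein_b.upper().rstrip("*"))[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    out_a, out_b, retained = [], [], []
    ia = ib = 0
    for col, (ra, rb) in enumerate(zip(row_a, row_b)):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia: 3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib: 3 * ib + 3])
            ib += 1
        if ra != "-" and rb != "-":
            retained.append(col)
    return CodonAlignment("".join(out_a), "".join(out_b), tuple(retained))


# ------------------------------------------------------------- estimates


@dataclass(frozen=True)
class KaKsEstimate:
    ka: float
    ks: float
    ratio: float  # nan when NA
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int
    na_reason: str | None = None

    @property
    def selection_class(self) -> str:
        return classify_selection(self)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(alignment: CodonAlignment) -> KaKsEstimate:
    """NG86 Ka, Ks and their ratio for a codon alignment.

    Site totals are averaged over the two sequences; the ratio is NA
    (nan, with `na_reason`) when Ks = 0 or a Jukes-Cantor correction is
    undefined.
    """
    if not alignment.retained:
        return KaKsEstimate(math.nan, math.nan, math.nan, 0.0, 0.0, 0.0, 0.0, 0,
                            na_reason="empty_alignment")
    n_a = s_a = n_b = s_b = nd = sd = 0.0
    for ca, cb in alignment.codon_pairs():
        na_, sa_ = ng86_sites(ca)
        nb_, sb_ = ng86_sites(cb)
        n_a += na_
        s_a += sa_
        n_b += nb_
        s_b += sb_
        d_n, d_s = _pathway_differences(ca, cb)
        nd += d_n
        sd += d_s
    n_sites = (n_a + n_b) / 2.0
    s_sites = (s_a + s_b) / 2.0
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    ka = _jukes_cantor(pn)
    ks = _jukes_cantor(ps)
    reason = None
    if math.isnan(ka) or math.isnan(ks):
        ratio = math.nan
        reason = "correction_undefined"
    elif ks == 0.0:
        ratio = math.nan
        reason = "ks_zero"
    else:
        ratio = ka / ks
    return KaKsEstimate(ka, ks, ratio, n_sites, s_sites, nd, sd,
                        len(alignment.retained), na_reason=reason)


def estimate_pair(protein_a: str, protein_b: str, cds_a: str, cds_b: str,
                  name_a: str = "seqA", name_b: str = "seqB") -> KaKsEstimate:
    """Convenience: align then estimate, with lexicographic canonicalization
    so estimate(a,b) == estimate(b,a) exactly."""
    if (protein_b, cds_b) < (protein_a, cds_a):
        protein_a, protein_b = protein_b, protein_a
        cds_a, cds_b = cds_b, cds_a
        name_a, name_b = name_b, name_a
    return ng86_pair(align_codons(protein_a, protein_b, cds_a, cds_b, name_a, name_b))


def classify_selection(estimate: KaKsEstimate) -> str:
    """positive / purifying / neutral by the ratio's position around 1; NA
    propagates."""
    ratio = estimate.ratio
    if estimate.na_reason is not None or math.isnan(ratio):
        return "NA"
    if ratio > 1.0:
        return "positive"
    if ratio < 1.0:
        return "purifying"
    return "neutral"


def og_kaks_distribution(og_members: dict[str, dict[str, list[str]]],
                         cds: dict[str, str],
                         proteins: dict[str, str]) -> dict[str, list[tuple[str, str, KaKsEstimate]]]:
    """Per-orthogroup Ka/Ks estimates over all cross-genome gene pairs.

    `og_members` maps og -> genome -> gene ids. Orthogroups present in a
    single genome yield an empty list (no cross-genome pair exists); an
    orthogroup in exactly two genomes with one gene each yields exactly
    one estimate.
    """
    out: dict[str, list[tuple[str, str, KaKsEstimate]]] = {}
    for og, by_genome in og_members.items():
        estimates = []
        genomes = sorted(by_genome)
        for gi, gj in itertools.combinations(genomes, 2):
            for ga in sorted(by_genome[gi]):
                for gb in sorted(by_genome[gj]):
                    est = estimate_pair(proteins[ga], proteins[gb],
                                        cds[ga], cds[gb], ga, gb)
                    estimates.append((ga, gb, est))
        out[og] = estimates
    return out
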