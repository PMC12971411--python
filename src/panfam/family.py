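"""Gene-family identification and typing.

The family set is built by composing two filters over a candidate pool:
a domain-hit filter (keep genes with at least one qualifying HMM hit,
E-value <= cutoff, default 1e-5) and a best-identity filter against a
reference protein set (strictly greater than 50% global identity by
default). Each family protein is then typed typical/atypical by the
~44-residue PSPG (Plant Secondary Product Glycosyltransferase) motif
near the UGT C-terminus, and assigned a phylogenetic group (A..Q) by
nearest labeled reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

# 44-residue PSPG consensus (UGT signature near the C-terminus).
PSPG_CONSENSUS = "WAPQVEVLAHPAVGCFVTHCGWNSTLESLSAGVPMVAWPLYAEQ"
PSPG_WIDTH = len(PSPG_CONSENSUS)


@dataclass(frozen=True)
class PspgModel:
    """Position weight model of fixed width: weights[i][aa] -> score."""

    weights: tuple[dict[str, float], ...]

    @property
    def width(self) -> int:
        return len(self.weights)

    @property
    def max_score(self) -> float:
        return sum(max(w.values()) for w in self.weights)

    def score_window(self, window: str) -> float:
        return sum(w.get(aa, 0.0) for w, aa in zip(self.weights, window))

    def best_score(self, protein: str) -> float:
        protein = protein.upper().rstrip("*")
        if len(protein) < self.width:
            return float("-inf")
        return max(
            self.score_window(protein[i: i + self.width])
            for i in range(len(protein) - self.width + 1)
        )


def default_pspg_model() -> PspgModel:
    """Consensus-indicator model: weight 1 for the consensus residue at
    each of the 44 positions, 0 otherwise (max score 44)."""
    return PspgModel(tuple({aa: 1.0} for aa in PSPG_CONSENSUS))


def load_pspg_model(path) -> PspgModel:
    """Load a position weight model from a TSV (columns: pos, aa, weight)."""
    table = pd.read_csv(path, sep="\t")
    weights: dict[int, dict[str, float]] = {}
    for row in table.itertuples():
        weights.setdefault(int(row.pos), {})[str(row.aa)] = float(row.weight)
    return PspgModel(tuple(weights[p] for p in sorted(weights)))


# -------------------------------------------------------------- filters


def filter_domain_hits(hits: pd.DataFrame, cutoff: float = 1e-5) -> set[str]:
    """Genes with at least one domain hit at E-value <= cutoff.

    `hits` uses the columns of :data:`panfam.io.DOMTBL_COLUMNS`.
    """
    if cutoff <= 0:
        raise ValueError("E-value cutoff must be positive")
    if hits.empty:
        return set()
    kept = hits.loc[hits["evalue"] <= cutoff, "gene_id"]
    return set(kept)


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


@lru_cache(maxsize=100_000)
def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the best global alignment.

    Identity = matching columns / aligned columns, where terminal gap
    columns are excluded from the denominator but internal gaps count.
    Inputs are canonicalized by lexicographic order so the function is
    exactly symmetric.
    """
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    seq_a = seq_a.upper().rstrip("*")
    seq_b = seq_b.upper().rstrip("*")
    alignment = _identity_aligner().align(seq_a, seq_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    # strip terminal gap columns (gap at either end of either row)
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    columns = end - start
    if columns == 0:
        return 0.0
    matches = sum(1 for a, b in zip(row_a[start:end], row_b[start:end]) if a == b and a != "-")
    return 100.0 * matches / columns


def identity_filter(candidates: dict[str, str], references: dict[str, str],
                    threshold: float = 50.0) -> set[str]:
    """Candidates whose best global identity to any reference is
    strictly greater than `threshold` percent."""
    if not 0 < threshold < 100:
        raise ValueError("identity threshold must be in (0, 100)")
    if not references:
        raise ValueError("empty reference set (missing query file?)")
    kept = set()
    for name, seq in candidates.items():
        best = max(global_identity(seq, ref) for ref in references.values())
        if best > threshold:
            kept.add(name)
    return kept


# --------------------------------------------------------------- typing


def classify_pspg(protein: str, model: PspgModel | None = None,
                  score_cutoff: float | None = None) -> str:
    """Type a protein 'typical' (PSPG motif present) or 'atypical'.

    Typical iff the best sliding-window score under the position weight
    model reaches `score_cutoff` (default 60% of the maximal attainable
    score). Proteins shorter than the model width are atypical, with a
    warning.
    """
    model = model or default_pspg_model()
    if score_cutoff is None:
        score_cutoff = 0.6 * model.max_score
    protein = protein.upper().rstrip("*")
    if len(protein) < model.width:
        warnings.warn(
            f"protein of length {len(protein)} shorter than motif width {model.width}; "
            "typed atypical",
            stacklevel=2,
        )
        return "atypical"
    return "typical" if model.best_score(protein) >= score_cutoff else "atypical"


def assign_group(protein: str, labeled_refs: list[tuple[str, str]]) -> str:
    """Group label of the highest-identity labeled reference.

    `labeled_refs` is a list of (sequence, group label); ties are broken
    by the lexicographically smallest group label.
    """
    if not labeled_refs:
        raise ValueError("no labeled references provided")
    best_label, best_identity = None, -1.0
    for seq, label in sorted(labeled_refs, key=lambda t: t[1]):
        ident = global_identity(protein, seq)
        if ident > best_identity:
            best_identity, best_label = ident, label
    return best_label


def name_family_ogs(occupancy: dict[str, int], total_copies: dict[str, int],
                    prefix: str = "UGT") -> dict[str, str]:
    """Stable sequential family labels for orthogroups.

    Ordering: descending occupancy, then descending total copy number,
    then orthogroup id; labels are `prefix`1, `prefix`2, ...
    """
    ordered = sorted(occupancy, key=lambda og: (-occupancy[og], -total_copies.get(og, 0), og))
    return {og: f"{prefix}{i}" for i, og in enumerate(ordered, start=1)}


# ---------------------------------------------------------- family table


def build_family_table(genes: pd.DataFrame, proteins: dict[str, str],
                       family_genes: set[str],
                       og_of_gene: dict[str, str],
                       labeled_refs: list[tuple[str, str]] | None = None,
                       model: PspgModel | None = None,
                       og_names: dict[str, str] | None = None) -> pd.DataFrame:
    """Assemble the per-gene family table (gene, genome, pspg_type, group,
    og, family_name) for genes passing the identification filters."""
    rows = []
    for row in genes.itertuples():
        if row.gene_id not in family_genes:
            continue
        prot = proteins[row.gene_id]
        pspg = classify_pspg(prot, model=model)
        group = assign_group(prot, labeled_refs) if labeled_refs else "unassigned"
        og = og_of_gene.get(row.gene_id, "")
        rows.append(
            (row.gene_id, row.genome, pspg, group, og,
             (og_names or {}).get(og, ""))
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "genome", "pspg_type", "group", "og", "family_name"]
    )
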