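"""Synthetic pan-genome generator with known ground truth.

Emits a fully self-contained bundle — per-genome GFF3 annotations, CDS
and protein FASTA, an OrthoFinder-style orthogroup table, domain-hit and
similarity tables, an outgroup genome — plus a truth table recording
every planted occupancy category, duplication mode, omega value and
PSPG type, so each downstream stage of the pipeline can be validated
offline against what was planted.

Layout of planted duplications (genome 1, two chromosomes): event
groups are separated by runs of scaffold genes longer than the
chainer's `max_gap`, so each planted pair is unambiguous under the
default collinearity parameters:

* WGD pairs form one parallel collinear block across chr1/chr2;
* TD pairs are rank-adjacent on chr1, PD pairs are 2-4 ranks apart on
  chr2 (each same-chromosome anchor group is kept smaller than
  `min_block_size` so it cannot itself form a block);
* TRD pairs put one gene inside a run that is collinear with the
  outgroup genome (the ancestral locus) and the partner elsewhere;
* DSD pairs sit across chromosomes, isolated from every block.

Codon evolution is a single-parameter process: single-nucleotide
proposals are uniform (Jukes-Cantor-like) and nonsynonymous proposals
are accepted with a probability scaled by omega (synonymous scaled by
1/omega when omega > 1), so the planted dN/dS equals omega in
expectation and is recoverable by the NG86 estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from panfam import io
from panfam.family import PSPG_CONSENSUS
from panfam.kaks import NUCLEOTIDES, STOP_CODONS, _CODON_TABLE, translate_codon
from panfam.pangenome import classify_og, soft_core_floor
from panfam.sv import StructuralVariant

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)

REFERENCE_GROUPS = ("A", "D", "E", "G", "L", "P")


class ConfigurationError(ValueError):
    pass


# ----------------------------------------------------------------- specs


@dataclass(frozen=True)
class OgSpec:
    """A batch of orthogroups to plant: occupancy category, how many,
    copy-count range per member genome, and PSPG typicality."""

    category: str
    n_ogs: int
    copy_range: tuple[int, int] = (1, 2)
    occupancy: int | None = None  # drawn from the category's range if None
    pspg_typical: bool = True


@dataclass(frozen=True)
class DupSpec:
    """Planted duplication events per mode (pairs)."""

    wgd: int = 6
    td: int = 3
    pd: int = 3
    trd: int = 3
    dsd: int = 3


@dataclass(frozen=True)
class SvSpec:
    """Structural-variant planting: counts, window fraction, additive
    expression effect (TPM units) and the negative-binomial noise model."""

    n_svs: int = 30
    frac_in_windows: float = 0.7
    effect_size: float = 40.0
    n_effect_genes: int = 2
    frac_low_dp: float = 0.15
    nb_mean: float = 50.0
    nb_size: float = 10.0
    n_background: int = 200  # non-family transcriptome rows (TPM realism)


def default_og_spec() -> tuple[OgSpec, ...]:
    return (
        OgSpec("core", 3),
        OgSpec("soft-core", 4),
        OgSpec("dispensable", 10),
        OgSpec("dispensable", 2, pspg_typical=False),
        OgSpec("private", 5),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_genomes: int = 10
    n_chromosomes: int = 2
    og_spec: tuple[OgSpec, ...] = field(default_factory=default_og_spec)
    dup_spec: DupSpec = field(default_factory=DupSpec)
    omega_grid: tuple[float, ...] = (0.2, 1.0, 2.0)
    sv_spec: SvSpec = field(default_factory=SvSpec)
    n_decoys: int = 2
    seed: int = 0
    # chainer parameters the planted layout is separated against
    max_gap: int = 25
    min_block_size: int = 5

    def validate(self) -> None:
        if self.n_genomes < 1 or self.n_chromosomes < 1:
            raise ConfigurationError("n_genomes and n_chromosomes must be positive")
        for spec in self.og_spec:
            if spec.n_ogs < 1:
                raise ConfigurationError("n_ogs must be positive")
            if spec.occupancy is not None and not 1 <= spec.occupancy <= self.n_genomes:
                raise ConfigurationError(
                    f"occupancy {spec.occupancy} outside [1, {self.n_genomes}]"
                )
            lo, hi = spec.copy_range
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"bad copy range {spec.copy_range}")
        d = self.dup_spec
        if min(d.wgd, d.td, d.pd, d.trd, d.dsd) < 0:
            raise ConfigurationError("duplication counts must be >= 0")
        if 0 < d.wgd < self.min_block_size:
            raise ConfigurationError(
                f"wgd events ({d.wgd}) below min_block_size ({self.min_block_size}): "
                "the planted block could not be detected"
            )
        if max(d.td, d.pd, d.trd, d.dsd) >= self.min_block_size:
            raise ConfigurationError(
                "td/pd/trd/dsd event counts must stay below min_block_size, or the "
                "planted anchors would themselves chain into a collinear block"
            )
        if any(d_ > 0 for d_ in (d.wgd, d.td, d.pd, d.trd, d.dsd)) and self.n_chromosomes < 2:
            raise ConfigurationError("duplication playground needs >= 2 chromosomes")
        if any(w <= 0 for w in self.omega_grid):
            raise ConfigurationError("omega values must be positive")
        s = self.sv_spec
        if s.effect_size < 0 or not 0 <= s.frac_in_windows <= 1 or not 0 <= s.frac_low_dp <= 1:
            raise ConfigurationError("bad sv_spec")


# ----------------------------------------------------------------- truth


@dataclass
class TruthTable:
    og_category: dict[str, str] = field(default_factory=dict)
    og_omega: dict[str, float] = field(default_factory=dict)
    og_group: dict[str, str] = field(default_factory=dict)
    pair_mode: dict[frozenset, str] = field(default_factory=dict)
    gene_typical: dict[str, bool] = field(default_factory=dict)
    gene_family: dict[str, bool] = field(default_factory=dict)


# ------------------------------------------------------------- sequences


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    )


def translate(cds: str) -> str:
    return "".join(
        translate_codon(cds[i: i + 3]) for i in range(0, len(cds) - len(cds) % 3, 3)
    ).rstrip("*")


def evolve_cds(cds: str, omega: float, n_events: int, rng: np.random.Generator,
               protected_codons: set[int] = frozenset()) -> str:
    """Apply `n_events` proposed single-nucleotide substitutions.

    Proposals hitting stop codons or protected codon positions are
    rejected; nonsynonymous proposals are accepted with probability
    min(1, omega) and synonymous ones with min(1, 1/omega)."""
    seq = list(cds)
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega)
    length = len(seq)
    for _ in range(n_events):
        site = int(rng.integers(length))
        codon_idx = site // 3
        if codon_idx in protected_codons:
            continue
        cur = seq[site]
        nt = NUCLEOTIDES[int(rng.integers(4))]
        if nt == cur:
            continue
        codon = "".join(seq[3 * codon_idx: 3 * codon_idx + 3])
        mutant = codon[: site % 3] + nt + codon[site % 3 + 1:]
        if mutant in STOP_CODONS:
            continue
        accept = p_syn if _CODON_TABLE[mutant] == _CODON_TABLE[codon] else p_nonsyn
        if rng.random() < accept:
            seq[site] = nt
    return "".join(seq)


@dataclass(frozen=True)
class CodonPairSim:
    seq_a: str
    seq_b: str
    omega: float
    branch_length: float


def simulate_codon_pair(n_codons: int, omega: float, branch_length: float,
                        seed: int) -> CodonPairSim:
    """Evolve a random ancestor along two branches of branch_length/2
    each under the scaled-omega process and return the two descendant
    CDS (equal length, no stop codons)."""
    if n_codons < 50:
        raise ConfigurationError("n_codons must be >= 50")
    if omega <= 0:
        raise ConfigurationError("omega must be positive")
    if branch_length < 0:
        raise ConfigurationError("branch_length must be >= 0")
    rng = np.random.default_rng(seed)
    sense = [c for c in sorted(_CODON_TABLE) if c not in STOP_CODONS]
    ancestor = "".join(rng.choice(sense, size=n_codons))
    length = 3 * n_codons
    events = int(rng.poisson(branch_length / 2 * length))
    seq_a = evolve_cds(ancestor, omega, events, rng)
    events = int(rng.poisson(branch_length / 2 * length))
    seq_b = evolve_cds(ancestor, omega, events, rng)
    return CodonPairSim(seq_a, seq_b, omega, branch_length)


# ------------------------------------------------------------- the bundle


@dataclass
class PanGenomeBundle:
    config: GeneratorConfig
    genes: pd.DataFrame  # gene_id, genome, chrom, start, end, strand, og
    cds: dict[str, str]
    proteins: dict[str, str]
    truth: TruthTable
    self_hits: pd.DataFrame  # BLAST6 columns, intra-genome homolog pairs
    outgroup_hits: pd.DataFrame
    outgroup_genes: pd.DataFrame
    domain_hits: pd.DataFrame
    references: list[tuple[str, str]]  # (sequence, group)
    genomes: list[str]
    dup_genome: str

    @property
    def og_table(self) -> pd.DataFrame:
        return self.genes[["og", "genome", "gene_id"]].rename(columns={"og": "og"})

    def chromosome_sequence(self, genome: str, chrom: str) -> str:
        """Deterministic random chromosome sequence long enough to hold
        every gene on it (plus 3 kb tail)."""
        if genome == "OUTG":
            gidx = self.config.n_genomes
            table = self.outgroup_genes
        else:
            gidx = self.genomes.index(genome)
            table = self.genes[self.genes["genome"] == genome]
        on_chrom = table[table["chrom"] == chrom]
        length = (int(on_chrom["end"].max()) if len(on_chrom) else 1000) + 3000
        cidx = int(chrom.removeprefix("chr").removeprefix("O") or 0)
        rng = np.random.default_rng([self.config.seed, 9001, gidx, cidx])
        return "".join(rng.choice(list(NUCLEOTIDES), size=length))

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in self.genomes:
            io.write_gff3(outdir / f"{genome}.gff3", self.genes[self.genes["genome"] == genome])
        io.write_gff3(outdir / "OUTG.gff3", self.outgroup_genes)
        all_ids = list(self.genes["gene_id"]) + list(self.outgroup_genes["gene_id"])
        io.write_fasta(outdir / "cds.fa", {g: self.cds[g] for g in all_ids})
        io.write_fasta(outdir / "prot.fa", {g: self.proteins[g] for g in all_ids})
        io.write_fasta(
            outdir / "refs.fa",
            {f"ref{grp}": seq for seq, grp in self.references},
            descriptions={f"ref{grp}": f"group={grp}" for _, grp in self.references},
        )
        io.write_orthogroups(outdir / "Orthogroups.tsv", self.og_table, self.genomes)
        io.write_domtbl(outdir / "domains.domtbl", self.domain_hits)
        io.write_blast_tab(outdir / "self_hits.tsv", self.self_hits)
        io.write_blast_tab(outdir / "outgroup_hits.tsv", self.outgroup_hits)
        truth_og = pd.DataFrame(
            sorted(
                (og, cat, self.truth.og_omega.get(og, float("nan")),
                 self.truth.og_group.get(og, ""))
                for og, cat in self.truth.og_category.items()
            ),
            columns=["og", "category", "omega", "group"],
        )
        io.write_tsv(outdir / "truth_og.tsv", truth_og)
        truth_pairs = pd.DataFrame(
            sorted((min(p), max(p), m) for p, m in self.truth.pair_mode.items()),
            columns=["gene_a", "gene_b", "mode"],
        )
        io.write_tsv(outdir / "truth_pairs.tsv", truth_pairs)
        truth_genes = pd.DataFrame(
            sorted(
                (g, self.truth.gene_typical.get(g, True), fam)
                for g, fam in self.truth.gene_family.items()
            ),
            columns=["gene_id", "typical", "family"],
        )
        io.write_tsv(outdir / "truth_genes.tsv", truth_genes)


# -------------------------------------------------------------- generator


class _GenomeLayout:
    """Accumulates ordered gene slots per (genome, chromosome)."""

    def __init__(self, genomes: list[str], n_chromosomes: int):
        self.slots: dict[tuple[str, str], list[str]] = {
            (g, f"chr{c + 1}"): [] for g in genomes for c in range(n_chromosomes)
        }
        self._rr: dict[str, int] = {g: 0 for g in genomes}

    def append(self, genome: str, chrom: str, gene_id: str) -> None:
        self.slots[(genome, chrom)].append(gene_id)

    def append_round_robin(self, genome: str, gene_id: str, n_chromosomes: int) -> str:
        chrom = f"chr{self._rr[genome] % n_chromosomes + 1}"
        self._rr[genome] += 1
        self.append(genome, chrom, gene_id)
        return chrom


def _draw_occupancy(spec: OgSpec, n: int, rng: np.random.Generator) -> int:
    if spec.occupancy is not None:
        return spec.occupancy
    floor = soft_core_floor(n)
    if spec.category == "core":
        return n
    if spec.category == "soft-core":
        if floor > n - 1:
            raise ConfigurationError(f"no soft-core occupancy exists for n={n}")
        return int(rng.integers(floor, n))  # [ceil(0.9n), n-1]
    if spec.category == "private":
        return 1
    if spec.category == "dispensable":
        if floor - 1 < 2:
            raise ConfigurationError(f"no dispensable occupancy exists for n={n}")
        return int(rng.integers(2, floor))  # [2, ceil(0.9n)-1]
    raise ConfigurationError(f"unknown category {spec.category!r}")


def generate_pangenome(config: GeneratorConfig | None = None) -> PanGenomeBundle:
    """Build the synthetic bundle. Deterministic: identical configs and
    seeds give identical bundles (and byte-identical files)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    genomes = [f"G{i + 1:02d}" for i in range(n)]
    dup_genome = genomes[0]
    truth = TruthTable()
    layout = _GenomeLayout(genomes, config.n_chromosomes)

    # --- ancestral reference proteins (one per phylogenetic group) ----
    prot_len = 320
    motif_at = 250
    references: list[tuple[str, str]] = []
    ancestors: dict[str, str] = {}
    for grp in REFERENCE_GROUPS:
        body = random_protein(rng, prot_len)
        seq = body[:motif_at] + PSPG_CONSENSUS + body[motif_at + len(PSPG_CONSENSUS):]
        ancestors[grp] = seq
        references.append((seq, grp))
    motif_codons = set(range(motif_at, motif_at + len(PSPG_CONSENSUS)))

    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    og_of_gene: dict[str, str] = {}
    gene_rows: list[tuple] = []  # filled after layout (coordinates need ranks)
    serial = {g: 0 for g in genomes}

    def new_gene_id(genome: str) -> str:
        serial[genome] += 1
        return f"{genome}g{serial[genome]:03d}"

    og_counter = 0

    def new_og() -> str:
        nonlocal og_counter
        og_counter += 1
        return f"OG{og_counter:04d}"

    def make_base(group: str, typical: bool, rng: np.random.Generator) -> str:
        """OG founder protein: ancestor with ~8% residues mutated outside
        the motif; atypical founders get the motif region shuffled away."""
        anc = list(ancestors[group])
        n_mut = int(0.08 * prot_len)
        for _ in range(n_mut):
            pos = int(rng.integers(prot_len))
            if pos in motif_codons:
                continue
            anc[pos] = AMINO_ACIDS[int(rng.integers(20))]
        if not typical:
            for pos in motif_codons:
                anc[pos] = AMINO_ACIDS[int(rng.integers(20))]
        return "".join(anc)

    def emit_member(gene_id: str, base_cds: str, omega: float, typical: bool,
                    og: str) -> None:
        protected = motif_codons if typical else frozenset()
        events = int(rng.poisson(0.02 * len(base_cds)))
        seq = evolve_cds(base_cds, omega, events, rng, protected_codons=protected)
        cds[gene_id] = seq + "TAA"
        proteins[gene_id] = translate(seq)
        og_of_gene[gene_id] = og
        truth.gene_typical[gene_id] = typical
        truth.gene_family[gene_id] = True

    # --- duplication playground (dup genome + outgroup) ----------------
    d = config.dup_spec
    gap = config.max_gap + 1
    self_hit_pairs: list[tuple[str, str]] = []
    outgroup_pairs: list[tuple[str, str]] = []
    outgroup_slots: list[str] = []
    outgroup_serial = 0

    def new_outgroup_id() -> str:
        nonlocal outgroup_serial
        outgroup_serial += 1
        return f"OUTGg{outgroup_serial:03d}"

    def playground_pair(mode: str) -> tuple[str, str]:
        """Create a homolog pair in the dup genome sharing one new OG."""
        og = new_og()
        grp = REFERENCE_GROUPS[og_counter % len(REFERENCE_GROUPS)]
        omega = float(config.omega_grid[og_counter % len(config.omega_grid)])
        base = make_base(grp, True, rng)
        base_cds = reverse_translate(base, rng)
        ga, gb = new_gene_id(dup_genome), new_gene_id(dup_genome)
        emit_member(ga, base_cds, omega, True, og)
        emit_member(gb, base_cds, omega, True, og)
        truth.og_category[og] = "private"
        truth.og_omega[og] = omega
        truth.og_group[og] = grp
        truth.pair_mode[frozenset((ga, gb))] = mode
        self_hit_pairs.append((ga, gb))
        return ga, gb

    def playground_filler() -> str:
        og = new_og()
        grp = REFERENCE_GROUPS[og_counter % len(REFERENCE_GROUPS)]
        base = make_base(grp, True, rng)
        gid = new_gene_id(dup_genome)
        emit_member(gid, reverse_translate(base, rng), 1.0, True, og)
        truth.og_category[og] = "private"
        truth.og_group[og] = grp
        return gid

    if any((d.wgd, d.td, d.pd, d.trd, d.dsd)):
        chr1: list[str] = []
        chr2: list[str] = []
        wgd_pairs = [playground_pair("WGD") for _ in range(d.wgd)]
        for ga, gb in wgd_pairs:
            chr1.append(ga)
            chr2.append(gb)
        chr1.extend(playground_filler() for _ in range(gap))
        chr2.extend(playground_filler() for _ in range(gap))
        dsd_pairs = [playground_pair("DSD") for _ in range(d.dsd)]
        for ga, gb in dsd_pairs:
            chr1.append(ga)
            chr2.append(gb)
        chr1.extend(playground_filler() for _ in range(gap))
        chr2.extend(playground_filler() for _ in range(gap))
        # TRD: ancestral-locus run on chr1, collinear with the outgroup
        trd_pairs = [playground_pair("TRD") for _ in range(d.trd)]
        run_len = max(config.min_block_size, d.trd + 2)
        run_genes = [ga for ga, _ in trd_pairs]
        run_genes += [playground_filler() for _ in range(run_len - len(run_genes))]
        for gene in run_genes:
            chr1.append(gene)
            out_id = new_outgroup_id()
            cds[out_id] = cds[gene]
            proteins[out_id] = proteins[gene]
            outgroup_slots.append(out_id)
            outgroup_pairs.append((gene, out_id))
        chr2.extend(gb for _, gb in trd_pairs)
        # TD: adjacent pairs on chr1; PD: nearby pairs on chr2
        for ga, gb in (playground_pair("TD") for _ in range(d.td)):
            chr1.extend((ga, gb))
        for i, (ga, gb) in enumerate(playground_pair("PD") for _ in range(d.pd)):
            chr2.append(ga)
            chr2.extend(playground_filler() for _ in range(i + 1))  # rank distance i+2
            chr2.append(gb)
        for gene in chr1:
            layout.append(dup_genome, "chr1", gene)
        for gene in chr2:
            layout.append(dup_genome, "chr2", gene)

    # --- planted occupancy orthogroups ---------------------------------
    for spec in config.og_spec:
        for _ in range(spec.n_ogs):
            og = new_og()
            grp = REFERENCE_GROUPS[og_counter % len(REFERENCE_GROUPS)]
            omega = float(config.omega_grid[og_counter % len(config.omega_grid)])
            occupancy = _draw_occupancy(spec, n, rng)
            members = sorted(rng.choice(n, size=occupancy, replace=False))
            base = make_base(grp, spec.pspg_typical, rng)
            base_cds = reverse_translate(base, rng)
            for gi in members:
                genome = genomes[int(gi)]
                copies = int(rng.integers(spec.copy_range[0], spec.copy_range[1] + 1))
                for _ in range(copies):
                    gid = new_gene_id(genome)
                    emit_member(gid, base_cds, omega, spec.pspg_typical, og)
                    layout.append_round_robin(genome, gid, config.n_chromosomes)
            truth.og_category[og] = classify_og(occupancy, n)
            if truth.og_category[og] != spec.category:
                raise AssertionError("planted occupancy inconsistent with category")
            truth.og_omega[og] = omega
            truth.og_group[og] = grp

    # --- decoys (fail the identification filters) -----------------------
    decoy_genome = genomes[1 % n]
    decoy_ids = []
    for _ in range(config.n_decoys):
        og = new_og()
        gid = new_gene_id(decoy_genome)
        prot = random_protein(rng, prot_len)
        cds[gid] = reverse_translate(prot, rng) + "TAA"
        proteins[gid] = prot
        og_of_gene[gid] = og
        truth.gene_family[gid] = False
        truth.gene_typical[gid] = False
        layout.append_round_robin(decoy_genome, gid, config.n_chromosomes)
        decoy_ids.append(gid)

    # --- coordinates from layout ---------------------------------------
    spacing = 3000
    for (genome, chrom), slot_genes in sorted(layout.slots.items()):
        for rank, gid in enumerate(slot_genes, start=1):
            start = 1000 + (rank - 1) * spacing
            end = start + len(cds[gid]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((gid, genome, chrom, start, end, strand, og_of_gene[gid]))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "genome", "chrom", "start", "end", "strand", "og"]
    )

    out_rows = []
    for rank, gid in enumerate(outgroup_slots, start=1):
        start = 1000 + (rank - 1) * spacing
        out_rows.append((gid, "OUTG", "chrO1", start, start + len(cds[gid]) - 1, "+"))
    outgroup_genes = pd.DataFrame(out_rows, columns=io.GENE_COLUMNS)

    # --- tabular side-channels ------------------------------------------
    def blast_rows(pairs, pident, evalue):
        rows = []
        for ga, gb in pairs:
            alen = min(len(proteins[ga]), len(proteins[gb]))
            rows.append((ga, gb, pident, alen, int(alen * (1 - pident / 100)), 0,
                         1, alen, 1, alen, evalue, 2.0 * alen))
        return pd.DataFrame(rows, columns=io.BLAST6_COLUMNS)

    self_hits = blast_rows(self_hit_pairs, 90.0, 1e-80)
    outgroup_hits = blast_rows(outgroup_pairs, 85.0, 1e-60)

    dom_rows = []
    for gid in sorted(truth.gene_family):
        if truth.gene_family[gid]:
            dom_rows.append((gid, "PF00201", 1e-30, 30, 300))
        else:
            dom_rows.append((gid, "PF00201", 1e-3, 30, 120))
    domain_hits = pd.DataFrame(dom_rows, columns=io.DOMTBL_COLUMNS)

    return PanGenomeBundle(
        config=config,
        genes=genes,
        cds=cds,
        proteins=proteins,
        truth=truth,
        self_hits=self_hits,
        outgroup_hits=outgroup_hits,
        outgroup_genes=outgroup_genes,
        domain_hits=domain_hits,
        references=references,
        genomes=genomes,
        dup_genome=dup_genome,
    )


# -------------------------------------------------------- SV + expression


@dataclass
class SvBundle:
    svs: list[StructuralVariant]
    counts: pd.DataFrame  # gene x sample (genome:tissue)
    meta: pd.DataFrame  # sample -> genome, tissue, condition
    lengths: pd.Series
    effect_genes: dict[str, set[str]]  # gene -> carrier genomes
    genomes: list[str]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sv_vcf(outdir / "svs.vcf", self.svs, self.genomes)
        io.write_tsv(outdir / "counts.tsv", self.counts, index=True)
        io.write_tsv(outdir / "samples.tsv", self.meta, index=True)
        io.write_tsv(outdir / "lengths.tsv", self.lengths.rename("length").to_frame(), index=True)


def write_sv_vcf(path, svs: list[StructuralVariant], genomes: list[str]) -> None:
    chroms = sorted({sv.chrom for sv in svs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genomes) + "\n")
        for sv in sorted(svs, key=lambda s: (s.chrom, s.pos, s.sv_id)):
            ref = "A" * sv.ref_len
            alt = "A" * sv.alt_len
            cells = []
            for g in genomes:
                gt = "1/1" if sv.presence.get(g, False) else "0/0"
                cells.append(f"{gt}:{sv.depth.get(g, 0)}")
            fh.write(f"{sv.chrom}\t{sv.pos}\t{sv.sv_id}\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"GT:DP\t" + "\t".join(cells) + "\n")


def _nb_draw(rng: np.random.Generator, mean, size_param: float):
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_presence_expression(n_genes: int, n_genomes: int, effect_size: float,
                                 n_effect_genes: int, rng: np.random.Generator,
                                 nb_mean: float = 50.0, nb_size: float = 10.0):
    """Presence/expression matrices for association calibration.

    Each gene gets a random non-constant binary presence vector over
    genomes; expression is negative-binomial around `nb_mean`, shifted
    additively by `effect_size` in carrier genomes for the first
    `n_effect_genes` genes. Returns (presence, expression, effect_genes).
    """
    if n_genomes < 5:
        raise ConfigurationError("association calibration needs >= 5 genomes")
    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    genomes = [f"G{i + 1:02d}" for i in range(n_genomes)]
    presence = np.zeros((n_genes, n_genomes), dtype=int)
    for i in range(n_genes):
        k = int(rng.integers(2, n_genomes - 1))
        presence[i, rng.choice(n_genomes, size=k, replace=False)] = 1
    effect = np.zeros((n_genes, 1))
    effect[:n_effect_genes, 0] = effect_size
    mean = nb_mean + effect * presence
    expr = _nb_draw(rng, mean, nb_size).astype(float)
    presence_df = pd.DataFrame(presence, index=gene_ids, columns=genomes)
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=genomes)
    return presence_df, expr_df, gene_ids[:n_effect_genes]


def plant_sv_effects(bundle: PanGenomeBundle, sv_spec: SvSpec | None = None,
                     seed: int | None = None, flank: int = 2000,
                     tissues: tuple[str, ...] = ("bud", "young leaf")) -> SvBundle:
    """Plant SVs (VCF, reference-genome coordinates) and gene x sample
    count matrices with additive expression effects for carrier genomes.

    A configurable fraction of per-genome depths falls below 20 to
    exercise the DP filter; effect-SV genotypes always pass it, so the
    planted carrier sets survive filtering intact.
    """
    spec = sv_spec or bundle.config.sv_spec
    rng = np.random.default_rng(
        [bundle.config.seed, 71] if seed is None else [seed, 71]
    )
    reference = bundle.genomes[0]
    other = [g for g in bundle.genomes if g != reference]
    ref_genes = bundle.genes[bundle.genes["genome"] == reference].reset_index(drop=True)
    if ref_genes.empty:
        raise ConfigurationError("reference genome has no genes")

    # expression follows orthogroup membership: a reference gene model is
    # expressed in a genome only when its orthogroup has a member there
    og_presence = bundle.genes.groupby("og")["genome"].agg(set).to_dict()
    full_occupancy = ref_genes[
        ref_genes["og"].map(lambda o: len(og_presence.get(o, set())) == len(bundle.genomes))
    ]

    n_window = int(round(spec.n_svs * spec.frac_in_windows))
    n_effect = min(spec.n_effect_genes, n_window)
    # planted-effect SVs target fully occupied genes so the shift is
    # observable across every genome
    effect_pool = full_occupancy if len(full_occupancy) >= n_effect else ref_genes
    # keep effect genes mutually distant so their windows (and SVs) never
    # overlap and dilute each other's association signal
    chosen: list[int] = []
    for idx in rng.permutation(len(effect_pool)):
        row = effect_pool.iloc[int(idx)]
        if all(
            effect_pool.iloc[j]["chrom"] != row.chrom
            or abs(int(effect_pool.iloc[j]["start"]) - int(row.start)) > 4 * flank
            for j in chosen
        ):
            chosen.append(int(idx))
        if len(chosen) == n_effect:
            break
    effect_targets = effect_pool.iloc[chosen].reset_index(drop=True)
    n_effect = len(effect_targets)

    def in_effect_window(row) -> bool:
        return any(
            e.chrom == row.chrom and abs(int(e.start) - int(row.start)) <= 3 * flank
            for e in effect_targets.itertuples()
        )

    pool = ref_genes[~ref_genes.apply(in_effect_window, axis=1)].reset_index(drop=True)
    if pool.empty:  # tiny reference genomes: accept possible window sharing
        pool = ref_genes
    random_targets = pool.iloc[
        rng.integers(len(pool), size=n_window - n_effect)
    ].reset_index(drop=True)
    target_rows = pd.concat([effect_targets, random_targets], ignore_index=True)
    effect_sv_idx = list(range(n_effect))  # first window SVs carry the effect

    svs: list[StructuralVariant] = []
    effect_genes: dict[str, set[str]] = {}
    for i in range(spec.n_svs):
        is_window = i < n_window
        is_effect = i in effect_sv_idx
        if is_window:
            row = target_rows.iloc[i]
            lo = max(1, int(row.start) - flank)
            hi = int(row.end) + flank
            pos = int(rng.integers(lo, hi + 1))
            chrom = row.chrom
        else:
            chrom = "chr1"
            max_end = int(ref_genes[ref_genes["chrom"] == chrom]["end"].max())
            pos = max_end + 10_000 + (i - n_window) * 5_000
        if rng.random() < 0.5:
            ref_len, alt_len = int(rng.integers(50, 301)), 1
        else:
            ref_len, alt_len = 1, int(rng.integers(50, 301))
        if is_effect:
            # balanced carrier split maximizes association power
            k = max(3, len(other) // 2)
        else:
            k = int(rng.integers(2, max(3, len(other))))
        carriers = {str(g) for g in np.array(other)[rng.choice(len(other), size=k, replace=False)]}
        presence = {g: g in carriers for g in bundle.genomes}
        depth = {}
        for g in bundle.genomes:
            low = (not is_effect) and rng.random() < spec.frac_low_dp
            depth[g] = int(rng.integers(5, 20)) if low else int(rng.integers(20, 61))
        svs.append(StructuralVariant(chrom, pos, ref_len, alt_len, presence, depth,
                                     sv_id=f"sv{i + 1:03d}"))
        if is_effect and spec.effect_size > 0:
            effect_genes.setdefault(row.gene_id, set()).update(carriers)

    gene_ids = list(ref_genes["gene_id"])
    samples, meta_rows = [], []
    for g in bundle.genomes:
        for t in tissues:
            sid = f"{g}:{t.replace(' ', '_')}"
            samples.append(sid)
            meta_rows.append((sid, g, t, "control", 0))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "genome", "tissue", "condition", "timepoint"]
    ).set_index("sample")

    og_of = dict(zip(ref_genes["gene_id"], ref_genes["og"]))
    mean = np.zeros((len(gene_ids), len(samples)))
    sample_genomes = list(meta["genome"])
    for gi, gid in enumerate(gene_ids):
        members = og_presence.get(og_of[gid], set())
        for si, genome in enumerate(sample_genomes):
            if genome not in members:
                continue  # family gene absent from this genome: no transcript
            m = spec.nb_mean
            if gid in effect_genes and genome in effect_genes[gid]:
                m += spec.effect_size
            mean[gi, si] = m
    bg_ids = [f"bg{i + 1:04d}" for i in range(spec.n_background)]
    bg_mean = np.full((len(bg_ids), len(samples)), spec.nb_mean)
    all_ids = gene_ids + bg_ids
    counts = pd.DataFrame(
        _nb_draw(rng, np.vstack([mean, bg_mean]), spec.nb_size).astype(float),
        index=all_ids, columns=samples,
    )
    counts.index.name = "gene_id"
    lengths = pd.Series(1000.0, index=pd.Index(all_ids, name="gene_id"))
    return SvBundle(svs, counts, meta, lengths, effect_genes, bundle.genomes)
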