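"""End-to-end pipeline: identify -> pan -> dup -> kaks -> sv -> expr.

`run_pipeline` drives every stage on either a synthetic bundle (the
`simulate` block of the run configuration) or user-provided files, and
`summarize` aggregates stage outputs into a machine-readable report
whose proportions are printed the way the field's tables are (half-up,
one decimal percent).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from panfam import duplication, expression, family, io, pangenome, sv
from panfam import kaks as kaks_mod
from panfam import simulate as sim
from panfam._stats import percent

DEFAULT_PARAMS = {
    "evalue": 1e-5,
    "min_identity": 50.0,
    "min_block_size": 5,
    "max_gap": 25,
    "td_max_gap": 1,
    "pd_max_gap": 10,
    "pair_min_identity": 30.0,
    "pair_max_evalue": 1e-10,
    "flank": 2000,
    "min_dp": 20,
    "alpha": 0.05,
    "n_perms": 100,
    "seed": 0,
}

ALL_STAGES = ("identify", "pan", "dup", "kaks", "sv", "expr")


def default_motif_table() -> pd.DataFrame:
    """Small built-in cis-element table (IUPAC patterns with functional
    categories) for promoter comparisons when none is supplied."""
    rows = [
        ("TATA-box", "TATAWAW", "growth"),
        ("CAAT-box", "CCAAT", "growth"),
        ("GT1-motif", "GGTTAA", "growth"),
        ("CAT-box", "GCCACT", "growth"),
        ("circadian", "CAANNNNATC", "growth"),
        ("ABRE", "ACGTGKC", "hormone"),
        ("ERE", "ATTTCAAA", "hormone"),
        ("TGA-element", "AACGAC", "hormone"),
        ("CGTCA-motif", "CGTCA", "hormone"),
        ("TCA-element", "CCATCTTTTT", "hormone"),
        ("MBS", "CAACTG", "stress"),
        ("LTR", "CCGAAA", "stress"),
        ("ARE", "AAACCA", "stress"),
        ("TC-rich", "ATTTTCTTCA", "stress"),
        ("W-box", "TTGACC", "stress"),
        ("G-box", "CACGTG", "stress"),
    ]
    return pd.DataFrame(rows, columns=["name", "pattern", "category"])


# ---------------------------------------------------------------- report


@dataclass
class Report:
    seed: int
    family_size: int = 0
    og_count: int = 0
    category_counts: dict[str, int] = field(default_factory=dict)
    category_shares: dict[str, float] = field(default_factory=dict)
    mode_counts: dict[str, int] = field(default_factory=dict)
    mode_shares: dict[str, float] = field(default_factory=dict)
    mode_total: int = 0
    mode_by_category: dict[str, dict[str, int]] = field(default_factory=dict)
    selection_counts: dict[str, int] = field(default_factory=dict)
    significant_sv_genes: dict[str, list[str]] = field(default_factory=dict)
    dosage: dict[str, dict[str, float]] = field(default_factory=dict)
    saturation: dict[str, list[float]] = field(default_factory=dict)
    pspg_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def mode_summary(counts: Mapping[str, int]) -> tuple[int, dict[str, float]]:
    """Total pair count and one-decimal percent share per duplication
    mode, half-up like printed tables."""
    total = int(sum(counts.values()))
    shares = {m: percent(c, total) for m, c in counts.items()}
    return total, shares


def category_summary(counts: Mapping[str, int]) -> tuple[int, dict[str, float]]:
    """Total orthogroup count and per-category percent shares."""
    total = int(sum(counts.values()))
    shares = {c: percent(v, total) for c, v in counts.items()}
    return total, shares


def summarize(stage_outputs: Mapping[str, Any], seed: int = 0) -> Report:
    """Aggregate stage outputs into a Report (deterministic)."""
    if not stage_outputs:
        raise ValueError("no stage outputs to summarize")
    report = Report(seed=seed)
    if "identify" in stage_outputs:
        fam = stage_outputs["identify"]["family_table"]
        report.family_size = int(len(fam))
        report.pspg_counts = fam["pspg_type"].value_counts().to_dict()
    if "pan" in stage_outputs:
        out = stage_outputs["pan"]
        cats = out["categories"]["category"]
        counts = {c: int((cats == c).sum()) for c in pangenome.CATEGORIES}
        report.og_count, report.category_shares = category_summary(counts)
        report.category_counts = counts
        curve = out["saturation"]
        report.saturation = {
            "k": [int(k) for k in curve.k],
            "pan_mean": [float(v) for v in curve.pan_mean],
            "core_mean": [float(v) for v in curve.core_mean],
        }
    if "dup" in stage_outputs:
        out = stage_outputs["dup"]
        counts = {m: 0 for m in duplication.MODES}
        for p in out["pairs"]:
            counts[p.mode] += 1
        report.mode_counts = counts
        report.mode_total, report.mode_shares = mode_summary(counts)
        report.mode_by_category = {
            m: {c: int(v) for c, v in row.items()}
            for m, row in out["crosstab"].iterrows()
        }
    if "kaks" in stage_outputs:
        classes = stage_outputs["kaks"]["classes"]
        report.selection_counts = {
            c: int(classes.count(c)) for c in ("positive", "purifying", "neutral", "NA")
        }
    if "sv" in stage_outputs:
        assoc = stage_outputs["sv"]["associations"]
        sig = assoc[assoc["significant"]]
        report.significant_sv_genes = {
            t: sorted(sub["gene_id"]) for t, sub in sig.groupby("tissue")
        }
    if "expr" in stage_outputs:
        report.dosage = {
            t: {"r": res.r, "p": res.p, "n": res.n}
            for t, res in stage_outputs["expr"]["dosage"].items()
        }
    return report


# --------------------------------------------------------------- pipeline


@dataclass
class RunConfig:
    simulate: sim.GeneratorConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        sim_cfg = None
        if "simulate" in raw:
            block = dict(raw["simulate"] or {})
            if "dup_spec" in block:
                block["dup_spec"] = sim.DupSpec(**block["dup_spec"])
            if "sv_spec" in block:
                block["sv_spec"] = sim.SvSpec(**block["sv_spec"])
            if "og_spec" in block:
                block["og_spec"] = tuple(
                    sim.OgSpec(**{**e, "copy_range": tuple(e.get("copy_range", (1, 2)))})
                    for e in block["og_spec"]
                )
            sim_cfg = sim.GeneratorConfig(**block)
        stages = tuple(raw.get("stages", ALL_STAGES))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        params = {**DEFAULT_PARAMS, **(raw.get("params") or {})}
        return cls(simulate=sim_cfg, stages=stages, params=params)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _candidate_pairs(hits: pd.DataFrame, positions: pd.DataFrame, params) -> dict[str, list]:
    """Intra-genome homolog pairs above the similarity floor, per genome."""
    genome_of = dict(zip(positions["gene_id"], positions["genome"]))
    pairs: dict[str, list] = {}
    kept = hits[
        (hits["evalue"] <= params["pair_max_evalue"])
        & (hits["pident"] >= params["pair_min_identity"])
    ]
    for row in kept.itertuples():
        ga, gb = row.query, row.subject
        if ga == gb:
            continue
        if genome_of.get(ga) != genome_of.get(gb) or genome_of.get(ga) is None:
            continue
        pairs.setdefault(genome_of[ga], []).append((ga, gb))
    return pairs


def run_pipeline(config: RunConfig, outdir) -> Report:
    """Run the enabled stages in dependency order and write artifacts.

    Currently self-contained runs (a `simulate` block) are the primary
    path; file-based inputs reuse the same stage functions through the
    readers in :mod:`panfam.io`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.params}
    if config.simulate is None:
        raise NotImplementedError(
            "file-based pipeline inputs: call the stage functions directly "
            "with the io readers; run_pipeline drives simulate-block configs"
        )
    bundle = sim.generate_pangenome(config.simulate)
    bundle.write(outdir / "sim")
    stage_outputs: dict[str, Any] = {}

    genes = bundle.genes
    family_genes: set[str] = set(genes["gene_id"])
    og_of_gene = dict(zip(genes["gene_id"], genes["og"]))

    if "identify" in config.stages:
        by_domain = family.filter_domain_hits(bundle.domain_hits, params["evalue"])
        candidates = {g: bundle.proteins[g] for g in sorted(by_domain)}
        refs = {f"ref{grp}": seq for seq, grp in bundle.references}
        family_genes = family.identity_filter(candidates, refs, params["min_identity"])
        occupancy, copies = {}, {}
        fam_frame = genes[genes["gene_id"].isin(family_genes)]
        for og, sub in fam_frame.groupby("og"):
            occupancy[og] = sub["genome"].nunique()
            copies[og] = len(sub)
        og_names = family.name_family_ogs(occupancy, copies)
        fam_table = family.build_family_table(
            genes, bundle.proteins, family_genes, og_of_gene,
            labeled_refs=bundle.references, og_names=og_names,
        )
        io.write_tsv(outdir / "family.tsv", fam_table)
        stage_outputs["identify"] = {"family_table": fam_table, "og_names": og_names}

    membership = categories = None
    if "pan" in config.stages:
        membership = pangenome.build_membership(
            bundle.og_table, family_genes, genomes=bundle.genomes
        )
        categories = pangenome.categorize(membership)
        curve = pangenome.saturation(membership, params["n_perms"], params["seed"])
        pav = pangenome.pav_matrix(membership, exclude_core=True)
        tallies = pangenome.per_genome_category_counts(membership, categories)
        io.write_tsv(outdir / "membership.tsv", membership, index=True)
        io.write_tsv(outdir / "categories.tsv", categories, index=True)
        io.write_tsv(outdir / "pav.tsv", pav, index=True)
        io.write_tsv(outdir / "saturation.tsv", curve.to_frame())
        io.write_tsv(outdir / "per_genome_counts.tsv", tallies, index=True)
        stage_outputs["pan"] = {
            "membership": membership, "categories": categories,
            "saturation": curve, "pav": pav, "tallies": tallies,
        }

    if "dup" in config.stages:
        positions = duplication.rank_genes(genes)
        by_genome = _candidate_pairs(bundle.self_hits, positions, params)
        out_positions = duplication.rank_genes(
            pd.concat([genes, bundle.outgroup_genes.assign(og="")], ignore_index=True)
        )
        outgroup_pairs = list(
            zip(bundle.outgroup_hits["query"], bundle.outgroup_hits["subject"])
        )
        outgroup_blocks = duplication.chain_collinear(
            outgroup_pairs, out_positions, params["min_block_size"], params["max_gap"]
        )
        all_pairs: list[duplication.DuplicationPair] = []
        for genome in sorted(by_genome):
            pairs = by_genome[genome]
            blocks = duplication.chain_collinear(
                pairs, positions, params["min_block_size"], params["max_gap"]
            )
            all_pairs.extend(
                duplication.classify_duplications(
                    pairs, blocks, outgroup_blocks, positions,
                    params["td_max_gap"], params["pd_max_gap"],
                )
            )
        og_category = (
            dict(zip(categories.index, categories["category"]))
            if categories is not None else {}
        )
        crosstab, shares = duplication.crosstab_mode_by_category(
            all_pairs, og_of_gene, og_category
        )
        pair_frame = pd.DataFrame(
            [(p.gene_a, p.gene_b, p.mode, p.evidence) for p in all_pairs],
            columns=["gene_a", "gene_b", "mode", "evidence"],
        )
        io.write_tsv(outdir / "dup_pairs.tsv", pair_frame)
        io.write_tsv(outdir / "dup_crosstab.tsv", crosstab, index=True)
        stage_outputs["dup"] = {"pairs": all_pairs, "crosstab": crosstab, "shares": shares}

    if "kaks" in config.stages:
        fam_frame = genes[genes["gene_id"].isin(family_genes)]
        og_members: dict[str, dict[str, list[str]]] = {}
        for row in fam_frame.itertuples():
            og_members.setdefault(row.og, {}).setdefault(row.genome, []).append(row.gene_id)
        multi = {og: m for og, m in og_members.items() if len(m) >= 2}
        dist = kaks_mod.og_kaks_distribution(multi, bundle.cds, bundle.proteins)
        rows, classes = [], []
        for og in sorted(dist):
            for ga, gb, est in dist[og]:
                cls = est.selection_class
                classes.append(cls)
                rows.append((ga, gb, og, est.ka, est.ks, est.ratio, cls, est.na_reason or ""))
        est_frame = pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "og", "ka", "ks", "ratio", "class", "reason"]
        )
        io.write_tsv(outdir / "kaks.tsv", est_frame)
        stage_outputs["kaks"] = {"estimates": est_frame, "classes": classes}

    sv_bundle = None
    tpm_matrix = None
    if "sv" in config.stages or "expr" in config.stages:
        sv_bundle = sim.plant_sv_effects(bundle, flank=params["flank"])
        sv_bundle.write(outdir / "sim")
        tpm_matrix = expression.tpm(sv_bundle.counts, sv_bundle.lengths)

    if "sv" in config.stages:
        filtered = sv.filter_svs(sv_bundle.svs, params["min_dp"])
        ref_genes = genes[genes["genome"] == bundle.genomes[0]]
        windows = [
            sv.GeneWindow.from_gene(r.gene_id, r.chrom, r.start, r.end, params["flank"])
            for r in ref_genes.itertuples()
        ]
        presence = sv.gene_sv_presence(filtered, windows, bundle.genomes)
        assoc_frames = []
        for tissue in sorted(sv_bundle.meta["tissue"].unique()):
            cols = sv_bundle.meta.index[sv_bundle.meta["tissue"] == tissue]
            expr_by_genome = tpm_matrix[cols].rename(
                columns=dict(zip(cols, sv_bundle.meta.loc[cols, "genome"]))
            )
            assoc_frames.append(
                sv.associate_all(presence, expr_by_genome, tissue, params["alpha"])
            )
        associations = pd.concat(assoc_frames, ignore_index=True)
        io.write_tsv(outdir / "sv_associations.tsv", associations)
        # promoter element comparison: reference vs the genome carrying
        # the most window-overlapping SVs
        carrier_load = {g: 0 for g in bundle.genomes[1:]}
        for svr in filtered:
            if any(sv.overlaps(svr, w) for w in windows):
                for g in svr.carriers:
                    if g in carrier_load:
                        carrier_load[g] += 1
        alt = max(sorted(carrier_load), key=lambda g: carrier_load[g]) if carrier_load else None
        elements = None
        if alt is not None:
            proms_ref, proms_alt = {}, {}
            chrom_cache: dict[tuple[str, str], str] = {}

            def chrom_seq(genome, chrom):
                key = (genome, chrom)
                if key not in chrom_cache:
                    chrom_cache[key] = bundle.chromosome_sequence(genome, chrom)
                return chrom_cache[key]

            for r in ref_genes.itertuples():
                proms_ref[r.gene_id] = sv.extract_promoter(
                    chrom_seq(bundle.genomes[0], r.chrom), r.start, r.end, r.strand
                )
            for r in genes[genes["genome"] == alt].itertuples():
                proms_alt[r.gene_id] = sv.extract_promoter(
                    chrom_seq(alt, r.chrom), r.start, r.end, r.strand
                )
            elements = sv.compare_elements(
                proms_ref, proms_alt, default_motif_table(),
                label_a=bundle.genomes[0], label_b=alt,
            )
            io.write_tsv(outdir / "cis_elements.tsv", elements)
        stage_outputs["sv"] = {
            "filtered": filtered, "presence": presence,
            "associations": associations, "elements": elements,
        }

    if "expr" in config.stages:
        fam_by_genome = (
            genes[genes["gene_id"].isin(family_genes)].groupby("genome").size().to_dict()
        )
        family_rows = [g for g in tpm_matrix.index if g in family_genes]
        profiles = expression.profile(
            tpm_matrix, family_rows, sv_bundle.meta, group_by="tissue"
        )
        dosage = {}
        for tissue in sorted(sv_bundle.meta["tissue"].unique()):
            rec = expression.dosage_records(
                tpm_matrix.loc[family_rows], sv_bundle.meta, fam_by_genome, tissue
            )
            dosage[tissue] = expression.dosage_correlation(
                rec["gene_count"], rec["total_tpm"]
            )
        io.write_tsv(outdir / "tpm.tsv", tpm_matrix, index=True)
        io.write_tsv(outdir / "profiles.tsv", profiles, index=True)
        stage_outputs["expr"] = {"tpm": tpm_matrix, "profiles": profiles, "dosage": dosage}

    report = summarize(stage_outputs, seed=params["seed"])
    report.to_json(outdir / "report.json")
    return report
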