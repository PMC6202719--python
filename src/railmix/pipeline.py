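"""End-to-end orchestration: counts/sequences in, reports out.

``run_pipeline`` sequences the stages (call -> QC -> mtDNA ID -> ancestry ->
site purity -> reference selection -> hybrid index/het -> classification ->
summaries), logs drops, and writes a machine-readable manifest with
parameters and output checksums. ``make_demo`` writes a self-contained
synthetic input set shaped like the study (11 sites, two admixed focal
sites).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, gtseq, introgression, io, mtdna, simdata
from .errors import DataError, ParameterError
from .panel import PanelSpec

log = logging.getLogger("railmix.pipeline")

STAGES = [
    "call",
    "sample_qc",
    "mtdna_id",
    "ancestry",
    "site_purity",
    "reference_selection",
    "hybrid_index_het",
    "classification",
    "summaries",
]


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run.

    Exactly one of ``counts`` (long-form read-count TSV) or ``genotypes``
    (called genotype CSV) must be given; when genotypes are supplied the
    calling stage is skipped. All thresholds default to the study's values.
    """

    panel: str
    counts: str | None = None
    genotypes: str | None = None
    mtdna_fasta: str | None = None
    king_vouchers: str | None = None
    clapper_vouchers: str | None = None
    sites: str | None = None
    # genotype calling
    min_depth: int = 10
    hom_fraction: float = 0.9
    het_low: float = 0.35
    het_high: float = 0.65
    # sample QC
    min_scored: int = 4
    max_missing_fraction: float = 0.30
    # mtDNA
    min_match: int = 6
    expected_sites: int = 8
    # ancestry
    ancestry_mode: str = "unsupervised"  # or "supervised"
    K: int = 2
    compare_K: list[int] = field(default_factory=lambda: [1, 2, 3])
    n_starts: int = 5
    q_pure: float = 0.98
    seed: int = 0
    outdir: str = "railmix_out"

    def __post_init__(self) -> None:
        if (self.counts is None) == (self.genotypes is None):
            raise ParameterError("give exactly one of counts or genotypes")
        if self.ancestry_mode not in ("unsupervised", "supervised"):
            raise ParameterError("ancestry_mode must be unsupervised or supervised")
        for name in ("hom_fraction", "het_low", "het_high", "max_missing_fraction", "q_pure"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages: list[dict] = []

    def record(self, stage: str, status: str, params: dict, outputs: list[Path]):
        self.stages.append(
            {
                "stage": stage,
                "status": status,
                "parameters": params,
                "outputs": [
                    {
                        "path": str(p.relative_to(self.outdir)),
                        "sha256": _sha256(p),
                    }
                    for p in outputs
                ],
            }
        )

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with path.open("w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    Every input sample ends up either in the final records or in
    ``drops.tsv`` with a reason. Reruns with identical config and seed
    produce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    panel = PanelSpec.read_tsv(config.panel)
    drops: list[tuple[str, str, str]] = []  # sample, stage, reason

    # --- stage 1: genotype calling -------------------------------------
    if config.counts is not None:
        counts = io.read_read_counts(config.counts)
        genotypes = gtseq.call_genotypes(
            counts,
            min_depth=config.min_depth,
            hom_fraction=config.hom_fraction,
            het_low=config.het_low,
            het_high=config.het_high,
        )
        path = outdir / "genotypes.csv"
        io.write_genotypes(genotypes, path)
        manifest.record(
            "call",
            "completed",
            {
                "min_depth": config.min_depth,
                "hom_fraction": config.hom_fraction,
                "het_low": config.het_low,
                "het_high": config.het_high,
            },
            [path],
        )
        log.info("called genotypes for %d samples x %d loci", *genotypes.shape)
    else:
        genotypes = io.read_genotypes(config.genotypes)
        manifest.record("call", "skipped", {"reason": "genotype CSV supplied"}, [])
        log.info("calling skipped: genotype CSV supplied")

    # --- stage 2: sample QC --------------------------------------------
    report = gtseq.qc_report(
        genotypes,
        max_missing_fraction=config.max_missing_fraction,
        min_scored=config.min_scored,
    )
    genotypes, dropped = gtseq.sample_qc(
        genotypes,
        max_missing_fraction=config.max_missing_fraction,
        min_scored=config.min_scored,
    )
    reasons = report.set_index("sample_id")["drop_reason"]
    drops += [(sid, "sample_qc", reasons[sid]) for sid in dropped]
    qc_path = outdir / "qc_report.tsv"
    io.write_tsv(report, qc_path)
    manifest.record(
        "sample_qc",
        "completed",
        {
            "min_scored": config.min_scored,
            "max_missing_fraction": config.max_missing_fraction,
            "n_dropped": len(dropped),
        },
        [qc_path],
    )
    log.info("sample QC dropped %d of %d samples", len(dropped), len(report))

    structure_path = outdir / "structure_input.txt"
    io.write_structure(genotypes, structure_path)

    # --- stage 3: mtDNA identification ---------------------------------
    mtdna_calls = None
    mtdna_outputs = []
    if config.mtdna_fasta and config.king_vouchers and config.clapper_vouchers:
        seqs = io.read_fasta(config.mtdna_fasta)
        kings = list(io.read_fasta(config.king_vouchers).values())
        clappers = list(io.read_fasta(config.clapper_vouchers).values())
        sites = mtdna.derive_diagnostic_sites(
            kings, clappers, expected_count=config.expected_sites
        )
        mtdna_calls = mtdna.classify_many(seqs, sites, min_match=config.min_match)
        mpath = outdir / "mtdna_calls.tsv"
        io.write_tsv(mtdna_calls, mpath)
        mtdna_outputs = [mpath]
        manifest.record(
            "mtdna_id",
            "completed",
            {"n_sites": len(sites), "min_match": config.min_match},
            mtdna_outputs,
        )
        log.info("classified %d mtDNA sequences at %d sites", len(seqs), len(sites))
    else:
        manifest.record("mtdna_id", "skipped", {"reason": "no mtDNA inputs"}, [])
        log.info("mtDNA stage skipped: inputs not provided")

    # --- stage 4: ancestry ---------------------------------------------
    if config.ancestry_mode == "supervised":
        result = ancestry.supervised_q(genotypes, panel)
        k_rows = []
    else:
        result = None
        k_rows = []
        for k in sorted(set(config.compare_K) | {config.K}):
            res_k = ancestry.unsupervised_em(
                genotypes,
                K=k,
                n_starts=config.n_starts,
                seed=config.seed,
                anchor_panel=panel if k == 2 else None,
            )
            k_rows.append(
                {
                    "K": k,
                    "mean_loglik": float(np.mean(res_k.start_logliks)),
                    "best_loglik": res_k.log_likelihood,
                    "converged": res_k.converged,
                }
            )
            if k == config.K:
                result = res_k
    drops += [(sid, "ancestry", "zero_scored_loci") for sid in result.flagged]
    q_df = result.q.reset_index().rename(columns={"index": "sample_id"})
    q_path = outdir / "q_matrix.tsv"
    io.write_tsv(q_df, q_path)
    outputs = [q_path]
    if k_rows:
        k_path = outdir / "k_comparison.tsv"
        io.write_tsv(pd.DataFrame(k_rows), k_path)
        outputs.append(k_path)
    manifest.record(
        "ancestry",
        "completed",
        {"mode": config.ancestry_mode, "K": config.K, "n_starts": config.n_starts,
         "seed": config.seed},
        outputs,
    )

    # --- stage 5: site purity ------------------------------------------
    membership = None
    if config.sites:
        membership = io.read_site_membership(config.sites).set_index("sample_id")[
            "site_id"
        ]
    if membership is not None and "KING" in result.q.columns:
        q_king = result.q["KING"].dropna()
        site_of = membership.reindex(q_king.index)
        q_by_site = {
            site: q_king[site_of == site].tolist()
            for site in pd.unique(site_of.dropna())
        }
        purities = ancestry.classify_sites(q_by_site, q_pure=config.q_pure)
        purity_df = pd.DataFrame(
            [(p.site_id, p.status, p.min_q_max) for p in purities],
            columns=["site_id", "status", "min_q_max"],
        )
        sp_path = outdir / "site_purity.tsv"
        io.write_tsv(purity_df, sp_path)
        manifest.record("site_purity", "completed", {"q_pure": config.q_pure}, [sp_path])
        log.info("site purity: %s", dict(zip(purity_df.site_id, purity_df.status)))
    else:
        purity_df = None
        manifest.record(
            "site_purity", "skipped", {"reason": "no site membership or no K=2 anchor"}, []
        )

    # --- stage 6: reference selection ----------------------------------
    # Parental allele frequencies re-estimated from pooled pure sites,
    # falling back to the panel's values when a species has no pure site.
    eff_panel = panel
    ref_info = {"king_source": "panel", "clapper_source": "panel"}
    if purity_df is not None and membership is not None:
        p_king = panel.p_king.copy()
        p_clapper = panel.p_clapper.copy()
        for species, status in (("king", "PURE_KING"), ("clapper", "PURE_CLAPPER")):
            pure_sites = purity_df.loc[purity_df.status == status, "site_id"]
            samples = membership.index[membership.isin(pure_sites)]
            samples = [s for s in samples if s in genotypes.index]
            if samples:
                sub = genotypes.loc[samples, panel.locus_ids]
                freq = (sub.sum(skipna=True) / (2 * sub.notna().sum())).to_numpy()
                ok = np.isfinite(freq)
                if species == "king":
                    p_king[ok] = freq[ok]
                else:
                    p_clapper[ok] = freq[ok]
                ref_info[f"{species}_source"] = f"{len(samples)} individuals from pure sites"
            else:
                log.info("no pure %s site; falling back to panel frequencies", species)
        eff_panel = panel.with_frequencies(p_king, p_clapper)
    ref_path = outdir / "reference_frequencies.tsv"
    eff_panel.loci.to_csv(ref_path, sep="\t", index=False)
    manifest.record("reference_selection", "completed", ref_info, [ref_path])

    # --- stage 7: hybrid index + heterozygosity ------------------------
    h_df = introgression.hybrid_index(genotypes, eff_panel)
    het_df = introgression.interspecific_het(genotypes[eff_panel.locus_ids])
    manifest.record("hybrid_index_het", "completed", {}, [])

    # --- stage 8: classification ---------------------------------------
    records = introgression.classify_records(h_df, het_df)
    rec_path = outdir / "introgression.tsv"
    io.write_tsv(records, rec_path)
    manifest.record("classification", "completed", {}, [rec_path])

    # --- stage 9: summaries --------------------------------------------
    outputs = []
    tri = introgression.triangle_data(records)
    tri_path = outdir / "triangle.tsv"
    io.write_tsv(tri, tri_path)
    outputs.append(tri_path)
    if membership is not None:
        with_sites = records.merge(
            membership.reset_index(), on="sample_id", how="left"
        )
        summary = introgression.site_summary(with_sites.dropna(subset=["site_id"]))
        sum_path = outdir / "site_summary.tsv"
        io.write_tsv(summary, sum_path)
        outputs.append(sum_path)
    if mtdna_calls is not None:
        cn = introgression.cytonuclear_table(mtdna_calls, records)
        cn_path = outdir / "cytonuclear.tsv"
        cn_out = cn.table.reset_index().rename(columns={"index": "mtdna_species"})
        io.write_tsv(cn_out, cn_path)
        outputs.append(cn_path)
        drops += [
            (row.sample_id, "cytonuclear", row.reason)
            for row in cn.unjoined.itertuples()
        ]
    drops_df = pd.DataFrame(
        sorted(set(drops)), columns=["sample_id", "stage", "reason"]
    )
    drops_path = outdir / "drops.tsv"
    io.write_tsv(drops_df, drops_path)
    outputs.append(drops_path)
    manifest.record("summaries", "completed", {}, outputs)

    manifest.write()
    log.info("run complete: %d stages, outputs in %s", len(manifest.stages), outdir)
    return {"stages": manifest.stages}


# ---------------------------------------------------------------------------
# demo dataset


def make_demo(
    seed: int = 0,
    outdir: str | Path = "demo",
    inject_hybrids: bool = True,
    mean_diff: float = 0.96,
    sd_diff: float = 0.08,
) -> RunConfig:
    """Write a self-contained synthetic input set shaped like the study.

    Eleven sites: two king reference sites, six pure clapper sites, two
    admixed focal sites carrying backcrosses (and one F1), and one southern
    site with a single backcross. Emits panel TSV, read counts, mtDNA and
    voucher FASTAs, site membership, truth table and a ready-to-run config.
    With ``inject_hybrids=False`` every non-reference bird is pure clapper.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(16)]
    panel = simdata.make_panel(
        13, mean_diff=mean_diff, sd_diff=sd_diff, floor=min(0.7, mean_diff), seed=seeds[0]
    )
    panel.write_tsv(outdir / "panel.tsv")

    site_designs: dict[str, dict[str, int]] = {
        "site01_LA_king": {"PURE_KING": 8},
        "site02_NC_king": {"PURE_KING": 6},
        "site03_NJ": {"PURE_CLAPPER": 8},
        "site04_NJ": {"PURE_CLAPPER": 8},
        "site05_NC": {"PURE_CLAPPER": 8},
        "site06_SC": {"PURE_CLAPPER": 8},
        "site07_eltham": {
            "PURE_CLAPPER": 10,
            "BC1_CLAPPER": 4,
            "BC2_CLAPPER": 3,
            "F1": 1,
        },
        "site08_mockhorn": {"PURE_CLAPPER": 10, "BC1_CLAPPER": 2},
        "site09_GA": {"PURE_CLAPPER": 6},
        "site10_GA": {"PURE_CLAPPER": 6},
        "site11_FL": {"PURE_CLAPPER": 5, "BC2_CLAPPER": 1},
    }
    if not inject_hybrids:
        site_designs = {
            site: {("PURE_KING" if "king" in site else "PURE_CLAPPER"): sum(d.values())}
            for site, d in site_designs.items()
        }

    genotype_parts, truth_parts, membership_rows = [], [], []
    for i, (site, design) in enumerate(site_designs.items()):
        g, t = simdata.simulate_cohort(
            panel, design, seed=seeds[1 + i], id_prefix=f"{site.split('_')[0]}_"
        )
        genotype_parts.append(g)
        truth_parts.append(t)
        membership_rows += [(sid, site) for sid in g.index]
    genotypes = pd.concat(genotype_parts)
    truth = pd.concat(truth_parts, ignore_index=True)
    membership = pd.DataFrame(membership_rows, columns=["sample_id", "site_id"])

    counts = simdata.simulate_read_counts(
        genotypes, depth_mean=120, depth_dispersion=4, error_rate=0.003, seed=seeds[12]
    )
    io.write_read_counts(counts, outdir / "read_counts.tsv")
    io.write_tsv(membership, outdir / "sites.tsv")
    io.write_tsv(truth, outdir / "truth.tsv")

    sim = simdata.simulate_mtdna(
        truth, background_divergence=0.002, seed=seeds[13]
    )
    io.write_fasta(sim.sequences, outdir / "mtdna.fasta")
    io.write_fasta(
        {"king_voucher_1": sim.king_consensus, "king_voucher_2": sim.king_consensus},
        outdir / "king_vouchers.fasta",
    )
    io.write_fasta(
        {
            "clapper_voucher_1": sim.clapper_consensus,
            "clapper_voucher_2": sim.clapper_consensus,
        },
        outdir / "clapper_vouchers.fasta",
    )

    config = RunConfig(
        panel=str(outdir / "panel.tsv"),
        counts=str(outdir / "read_counts.tsv"),
        mtdna_fasta=str(outdir / "mtdna.fasta"),
        king_vouchers=str(outdir / "king_vouchers.fasta"),
        clapper_vouchers=str(outdir / "clapper_vouchers.fasta"),
        sites=str(outdir / "sites.tsv"),
        seed=seed,
        outdir=str(outdir / "out"),
    )
    config.to_yaml(outdir / "config.yaml")
    return config
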