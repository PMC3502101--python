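"""End-to-end orchestration: simulate -> volatility -> usage -> dnds -> associate.

A run is driven by a flat plain-text config; every stage writes TSVs into the
output directory and a JSON manifest records the resolved configuration,
derived seeds, stage attrition counts and output checksums, so a run is
auditable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc
from . import io as cvio
from . import synthetic, usage as usage_mod
from .genetic_code import MutationModel
from .pairwise import align_proteins, alignment_coverage, backtranslate_alignment, m0_fit, ng86_dnds
from .usage import rscu as rscu_fn, count_codons
from .volatility import CodingSequence, RejectionRecord, genome_scan, validate_cds

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Flat run configuration; defaults reproduce the study's stated constants
    (kappa 4.1, P threshold 1e-6, 100 bp length filter, 5% axis-inertia
    cutoff, high-expression quantile 0.167)."""

    # analysis thresholds
    kappa: float = 4.1
    p_threshold: float = 1e-6
    min_gene_length_bp: int = 100
    high_expression_quantile: float = 0.167
    axis_inertia_cutoff: float = 0.05
    pvalue_method: str = "exact_normal"  # or "monte_carlo"
    mc_samples: int = 100_000
    # simulation stage (used when input_fasta is empty)
    n_genes: int = 600
    min_codons: int = 34
    max_codons: int = 800
    gc3_bias: float = 0.7
    gc3_sd: float = 0.15
    selection_strength: float = 0.0
    expression_mean: float = 6.44
    expression_sd: float = 2.02
    # dnds stage
    dnds_enabled: bool = True
    dnds_method: str = "ng86"  # "ng86", "m0" or "both"
    n_ortholog_pairs: int = 60
    ortholog_t: float = 0.5
    ortholog_kappa: float = 4.1
    omega_geometric_mean: float = 0.3
    omega_log_sd: float = 0.5
    fragment_fraction: float = 0.3
    # io
    input_fasta: str = ""
    expression_tsv: str = ""
    output_dir: str = "codonvol_run"
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.kappa > 0, "kappa must be positive"),
            (0 < self.p_threshold < 1, "p_threshold must lie in (0, 1)"),
            (self.min_gene_length_bp >= 3, "min_gene_length_bp must be >= 3"),
            (0 < self.high_expression_quantile < 1, "high_expression_quantile must lie in (0, 1)"),
            (0 <= self.axis_inertia_cutoff < 1, "axis_inertia_cutoff must lie in [0, 1)"),
            (self.pvalue_method in ("exact_normal", "monte_carlo"), "unknown pvalue_method"),
            (self.dnds_method in ("ng86", "m0", "both"), "unknown dnds_method"),
            (0 < self.fragment_fraction <= 1, "fragment_fraction must lie in (0, 1]"),
            (self.seed >= 0, "seed must be non-negative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import ast

        values: dict[str, object] = {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in names:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                try:
                    values[key] = ast.literal_eval(raw.strip())
                except (ValueError, SyntaxError):
                    values[key] = raw.strip()
        cfg = cls(**values)  # type: ignore[arg-type]
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    volatility: pd.DataFrame
    usage: pd.DataFrame
    inertia: pd.DataFrame
    dnds: pd.DataFrame | None
    report: assoc.AssociationReport | None
    manifest: dict


def _simulate_stage(config: RunConfig, outdir: Path, seed: int):
    spec = synthetic.SyntheticGenomeSpec(
        n_genes=config.n_genes, min_codons=config.min_codons, max_codons=config.max_codons,
        gc3_bias=config.gc3_bias, gc3_sd=config.gc3_sd,
        selection_strength=config.selection_strength,
        expression_mean=config.expression_mean, expression_sd=config.expression_sd,
        seed=seed,
    )
    genome = synthetic.generate_genome(spec)
    cvio.write_fasta([(c.gene_id, c.nucleotides) for c in genome.sequences],
                     outdir / "genome.fasta")
    cvio.write_tsv(genome.expression.reset_index(), outdir / "expression.tsv")
    cvio.write_tsv(genome.truth.reset_index(), outdir / "truth.tsv")
    return genome


def _dnds_stage(config: RunConfig, sequences: list[CodingSequence], outdir: Path,
                seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n_pairs = min(config.n_ortholog_pairs, len(sequences))
    chosen = rng.choice(len(sequences), size=n_pairs, replace=False)
    omegas = np.exp(rng.normal(np.log(config.omega_geometric_mean), config.omega_log_sd,
                               size=n_pairs))
    child = np.random.SeedSequence(seed).generate_state(2 * n_pairs) % (2**31)
    methods = {"ng86": ("NG86",), "m0": ("M0",), "both": ("NG86", "M0")}[config.dnds_method]
    rows = []
    for k, (idx, omega_true) in enumerate(zip(chosen, omegas)):
        cds = sequences[int(idx)]
        try:
            sim = synthetic.OrthologSimSpec(
                omega=float(omega_true), kappa=config.ortholog_kappa, t=config.ortholog_t,
                seed=int(child[2 * k]),
            )
            _, diverged = synthetic.evolve_pair(cds, sim)
            fragment = synthetic.truncate_to_fragment(
                diverged, config.fragment_fraction, seed=int(child[2 * k + 1])
            )
            pa = align_proteins(cds.protein(), fragment.protein(), mode="local")
            ca = backtranslate_alignment(pa, cds, fragment)
            cov = alignment_coverage(ca, cds.n_codons)
            for method in methods:
                est = ng86_dnds(ca) if method == "NG86" else m0_fit(ca)
                rows.append({
                    "gene_id": cds.gene_id, "method": method,
                    "dN": est.dN, "dS": est.dS, "omega": est.omega,
                    "kappa_hat": est.kappa_hat, "t_hat": est.t_hat, "lnL": est.lnL,
                    "coverage_pct": cov, "omega_true": float(omega_true),
                    "flags": ";".join(est.flags),
                })
        except Exception as exc:  # noqa: BLE001 — a bad pair must not kill the stage
            logger.warning("dnds: pair %s failed: %s", cds.gene_id, exc)
            rows.append({"gene_id": cds.gene_id, "method": "failed", "dN": np.nan,
                         "dS": np.nan, "omega": np.nan, "kappa_hat": np.nan,
                         "t_hat": np.nan, "lnL": np.nan, "coverage_pct": np.nan,
                         "omega_true": float(omega_true), "flags": f"error:{exc}"})
    df = pd.DataFrame(rows)
    cvio.write_tsv(df, outdir / "dnds.tsv")
    return df


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in dependency order.

    A failure inside the dnds stage is logged and the association step simply
    runs without the omega comparison; config errors abort before any stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    manifest: dict = {
        "codonvol_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {"simulate": int(seeds[0]), "volatility": int(seeds[1]),
                        "dnds": int(seeds[2])},
        "counts": {},
        "notices": [],
    }
    config.to_file(outdir / "config_resolved.txt")

    # --- inputs ------------------------------------------------------------
    expression: pd.Series | None = None
    if config.input_fasta:
        records = cvio.read_fasta(config.input_fasta)
        raw = [(rid, seq) for rid, seq in records]
        if config.expression_tsv:
            expression = cvio.read_expression(config.expression_tsv)
    else:
        genome = _simulate_stage(config, outdir, int(seeds[0]))
        raw = [(c.gene_id, c.nucleotides) for c in genome.sequences]
        expression = genome.expression

    # --- validation --------------------------------------------------------
    sequences: list[CodingSequence] = []
    rejections: list[RejectionRecord] = []
    for rid, seq in raw:
        out = validate_cds(seq, rid)
        (sequences if isinstance(out, CodingSequence) else rejections).append(out)  # type: ignore[arg-type]
    cvio.write_tsv(
        pd.DataFrame([{"gene_id": r.gene_id, "reason": r.reason, "detail": r.detail}
                      for r in rejections],
                     columns=["gene_id", "reason", "detail"]),
        outdir / "rejections.tsv",
    )
    manifest["counts"]["input_records"] = len(raw)
    manifest["counts"]["validated"] = len(sequences)
    manifest["counts"]["rejected"] = len(rejections)
    logger.info("validation: %d of %d records accepted", len(sequences), len(raw))
    if len(sequences) < 3:
        raise StageError("fewer than 3 validated sequences; cannot analyse")

    # --- volatility --------------------------------------------------------
    model = MutationModel(config.kappa)
    vol = genome_scan(
        sequences, model=model, threshold=config.p_threshold,
        method=config.pvalue_method, n_samples=config.mc_samples, seed=int(seeds[1]),
    )
    cvio.write_tsv(vol, outdir / "volatility.tsv")
    manifest["counts"]["elevated_volatility"] = int(vol["elevated_flag"].sum())

    # --- usage -------------------------------------------------------------
    per_gene, inertia, excluded = usage_mod.usage_axes(
        sequences, min_length_bp=config.min_gene_length_bp,
        axis_inertia_cutoff=config.axis_inertia_cutoff,
    )
    cvio.write_tsv(per_gene.reset_index(), outdir / "usage.tsv")
    cvio.write_tsv(inertia, outdir / "inertia.tsv")
    totals = np.zeros(64, dtype=int)
    for cds in sequences:
        totals += count_codons(cds)
    genome_rscu = rscu_fn(totals).rename("rscu").rename_axis("codon").reset_index()
    cvio.write_tsv(genome_rscu, outdir / "rscu.tsv")
    manifest["counts"]["usage_excluded_short"] = len(excluded)

    # --- dnds --------------------------------------------------------------
    dnds_df: pd.DataFrame | None = None
    if config.dnds_enabled:
        try:
            dnds_df = _dnds_stage(config, sequences, outdir, int(seeds[2]))
        except Exception as exc:  # noqa: BLE001 — partial failure tolerated by contract
            logger.error("dnds stage failed (%s); association will omit omega", exc)
            manifest["notices"].append(f"dnds stage failed: {exc}")
    else:
        manifest["notices"].append("dnds stage disabled; omega comparison skipped")

    # --- association -------------------------------------------------------
    gmt = assoc.build_metric_table(volatility=vol, usage=per_gene, expression=expression)
    if dnds_df is not None and len(dnds_df):
        # omega exists only for the sampled ortholog subset; join it as an
        # optional column so the genome-wide comparisons keep all genes.
        primary = "NG86" if config.dnds_method in ("ng86", "both") else "M0"
        omega_col = (dnds_df[dnds_df["method"] == primary]
                     .drop_duplicates("gene_id").set_index("gene_id")[["omega"]])
        gmt = gmt.join(omega_col, how="left")
    if expression is not None and len(gmt):
        gmt["high_expression_flag"] = assoc.select_high_expression(
            gmt["expression"], quantile=config.high_expression_quantile
        )
    report = assoc.association_report(gmt)
    cvio.write_tsv(report.to_frame(), outdir / "association.tsv")
    cvio.write_tsv(report.overlay_frame(), outdir / "overlays.tsv")
    manifest["notices"].extend(f"comparison skipped: {s}" for s in report.skipped)

    # --- manifest ----------------------------------------------------------
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        outdir=outdir, volatility=vol, usage=per_gene, inertia=inertia,
        dnds=dnds_df, report=report, manifest=manifest,
    )
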