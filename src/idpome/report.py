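"""Whole-pipeline workflows: profile, compare, overlap, simulate.

Each workflow is pure with respect to (inputs, config, seed): rerunning with
the same arguments rewrites byte-identical TSVs. Figures are secondary
outputs; the tables are the contract. A plain-text run log records every
skipped protein (sequence validation, LLPS length filter) so that
parsed = analyzed + skipped always reconciles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import plots
from .chcdf import CDFBoundary, calibrate_cdf_boundary, chcdf_points, quadrant_contingency
from .classify import ClassificationThresholds, proteome_summary
from .disorder import get_predictor, table_predictor
from .io import Proteome, RunLog, read_fasta, read_score_table, overlap_split, write_fasta
from .llps import LLPSConfig, analyze_proteome, cumulative_ps_curve, recall_auc
from .stats import chi_squared_test, one_way_anova, pairwise_t, tukey_hsd
from .synthetic import (
    Archetype,
    SyntheticProteomeSpec,
    generate_proteome,
    generate_reference_sets,
    write_labels,
)

__all__ = ["ConfigError", "RunConfig", "run_profile", "run_compare", "run_overlap", "run_simulate"]


class ConfigError(ValueError):
    """Invalid run configuration (as opposed to unreadable input data)."""


@dataclass
class RunConfig:
    """Reproducible manifest for a multi-proteome run.

    ``proteomes`` maps labels to FASTA paths; ``reference`` names the
    proteome used for overlap splits and recall AUC. ``scores`` optionally
    maps a predictor name to a per-residue score-table path, injected into
    the predictor registry for this run.
    """

    proteomes: dict[str, str]
    out_dir: str = "idpome_out"
    reference: str | None = None
    predictor: str = "foldindex"
    scores: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    strict_sequences: bool = False
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    llps: LLPSConfig = field(default_factory=LLPSConfig)

    def __post_init__(self) -> None:
        if not self.proteomes:
            raise ConfigError("at least one proteome is required")
        if self.reference is not None and self.reference not in self.proteomes:
            raise ConfigError(f"reference label {self.reference!r} not among proteomes")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML manifest; keyword overrides (CLI flags) win."""
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = {
            "proteomes", "out_dir", "reference", "predictor", "scores",
            "seed", "strict_sequences",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as err:
            raise ConfigError(str(err)) from err


def _load_proteomes(config: RunConfig, log: RunLog) -> dict[str, Proteome]:
    out = {}
    for label, path in config.proteomes.items():
        out[label] = read_fasta(path, label, strict=config.strict_sequences, log=log)
    return out


def _resolve_predictor(config: RunConfig):
    if config.predictor in config.scores:
        table = read_score_table(config.scores[config.predictor], "per_residue")
        return table_predictor(table, config.predictor)
    return get_predictor(config.predictor)


def _boundary(config: RunConfig, predictor) -> CDFBoundary:
    ordered, disordered = generate_reference_sets()
    return calibrate_cdf_boundary(ordered, disordered, predictor)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_profile(config: RunConfig) -> dict[str, Path]:
    """Per-proteome profiling: disorder summaries, tiers, CH–CDF, PS-IDRs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    proteomes = _load_proteomes(config, log)
    predictor = _resolve_predictor(config)
    boundary = _boundary(config, predictor)
    outputs: dict[str, Path] = {}
    curves: dict[str, pd.DataFrame] = {}
    for label, proteome in proteomes.items():
        profiles = {r.id: predictor(r.sequence, r.id) for r in proteome}
        summary = proteome_summary(proteome, profiles, config.thresholds)
        outputs[f"{label}_disorder"] = _write(summary["table"], out_dir / f"{label}_disorder.tsv")
        tiers = pd.DataFrame(
            {
                "tier": [t.value for t in summary["counts"]],
                "count": list(summary["counts"].values()),
                "percent": [summary["percentages"][t.value] for t in summary["counts"]],
            }
        )
        outputs[f"{label}_tiers"] = _write(tiers, out_dir / f"{label}_tiers.tsv")
        points = chcdf_points(proteome, boundary, predictor)
        outputs[f"{label}_chcdf"] = _write(points, out_dir / f"{label}_chcdf.tsv")
        fig, ax = plt.subplots(figsize=(5, 5))
        plots.chcdf_scatter(points, title=label, ax=ax)
        fig.savefig(out_dir / f"{label}_chcdf.png", dpi=120)
        plt.close(fig)
        ps = analyze_proteome(proteome, config.llps, log=log)
        ps_table = pd.DataFrame(
            {
                "protein_id": list(ps),
                "n_regions": [len(p.regions) for p in ps.values()],
                "max_region_length": [p.max_region_length for p in ps.values()],
                "ps_score": [p.ps_score for p in ps.values()],
            }
        )
        outputs[f"{label}_ps"] = _write(ps_table, out_dir / f"{label}_ps.tsv")
        if ps:
            curve = cumulative_ps_curve(ps)
            curves[label] = curve
            outputs[f"{label}_ps_curve"] = _write(curve, out_dir / f"{label}_ps_curve.tsv")
    if curves:
        fig, ax = plt.subplots(figsize=(6, 4))
        plots.ps_curve_plot(curves, ax=ax)
        fig.savefig(out_dir / "ps_curves.png", dpi=120)
        plt.close(fig)
    log.write(out_dir / "run.log")
    outputs["run_log"] = out_dir / "run.log"
    return outputs


def _metric_groups(
    proteomes: Mapping[str, Proteome], predictor, llps_config: LLPSConfig
) -> dict[str, dict[str, list[float]]]:
    """Per-proteome ADS, PPDR and ps_score vectors."""
    from .classify import ads as _ads, ppdr as _ppdr

    groups: dict[str, dict[str, list[float]]] = {"ads": {}, "ppdr": {}, "ps_score": {}}
    for label, proteome in proteomes.items():
        profs = [predictor(r.sequence, r.id) for r in proteome]
        groups["ads"][label] = [_ads(p) for p in profs]
        groups["ppdr"][label] = [_ppdr(p) for p in profs]
        ps = analyze_proteome(proteome, llps_config)
        groups["ps_score"][label] = [p.ps_score for p in ps.values()]
    return groups


def run_compare(
    config: RunConfig, quadrant_table: str | Path | None = None
) -> dict[str, Path]:
    """Cross-proteome statistics: ANOVA/Tukey/pairwise t per metric, quadrant
    χ², and recall AUC against the reference proteome (if one is named).

    *quadrant_table* optionally injects an externally computed proteome ×
    quadrant count TSV (first column proteome label, then Q1–Q4); when
    given, the χ² report is computed from those counts instead of the
    pipeline's own quadrant assignments.
    """
    if len(config.proteomes) < 2:
        raise ConfigError("compare requires at least two proteomes")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    proteomes = _load_proteomes(config, log)
    predictor = _resolve_predictor(config)
    boundary = _boundary(config, predictor)
    outputs: dict[str, Path] = {}

    groups = _metric_groups(proteomes, predictor, config.llps)
    anova_rows = []
    for metric, per_label in groups.items():
        labels = list(per_label)
        vectors = [per_label[l] for l in labels]
        if any(len(v) < 2 for v in vectors):
            continue
        res = one_way_anova(vectors)
        anova_rows.append((metric, res.f_stat, res.df_between, res.df_within, res.p_value))
        outputs[f"tukey_{metric}"] = _write(
            tukey_hsd(vectors, labels), out_dir / f"tukey_{metric}.tsv"
        )
        outputs[f"pairwise_{metric}"] = _write(
            pairwise_t(vectors, labels), out_dir / f"pairwise_{metric}.tsv"
        )
    outputs["anova"] = _write(
        pd.DataFrame(anova_rows, columns=["metric", "F", "df_between", "df_within", "p"]),
        out_dir / "anova.tsv",
    )

    if quadrant_table is not None:
        counts = pd.read_csv(quadrant_table, sep="\t", index_col=0)
    else:
        points = {
            label: chcdf_points(proteome, boundary, predictor)
            for label, proteome in proteomes.items()
        }
        counts = quadrant_contingency(points)
    counts.to_csv(out_dir / "quadrant_contingency.tsv", sep="\t")
    outputs["quadrant_contingency"] = out_dir / "quadrant_contingency.tsv"
    # zero-margin quadrants/proteomes carry no information for the test
    counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    chi = chi_squared_test(counts.to_numpy())
    chi_report = pd.DataFrame(
        {"chi2": [chi.chi2], "dof": [chi.dof], "p": [chi.p_value]}
    )
    outputs["chi2"] = _write(chi_report, out_dir / "chi2.tsv")
    expected = pd.DataFrame(chi.expected, index=counts.index, columns=counts.columns)
    expected.to_csv(out_dir / "chi2_expected.tsv", sep="\t", float_format="%.4f")
    outputs["chi2_expected"] = out_dir / "chi2_expected.tsv"

    if config.reference is not None:
        ref_scores = groups["ps_score"][config.reference]
        rows = []
        for label in proteomes:
            if label == config.reference:
                continue
            rows.append((label, recall_auc(groups["ps_score"][label], ref_scores)))
        outputs["recall_auc"] = _write(
            pd.DataFrame(rows, columns=["proteome", "recall_auc"]),
            out_dir / "recall_auc.tsv",
        )
    log.write(out_dir / "run.log")
    outputs["run_log"] = out_dir / "run.log"
    return outputs


def run_overlap(config: RunConfig) -> dict[str, Path]:
    """Overlap/unique split of each proteome against the reference, with
    ANOVA of ADS, PPDR and ps_score between the two membership groups."""
    if config.reference is None:
        raise ConfigError("overlap analysis requires a reference label")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    proteomes = _load_proteomes(config, log)
    predictor = _resolve_predictor(config)
    reference = proteomes[config.reference]
    outputs: dict[str, Path] = {}
    stat_rows = []
    for label, proteome in proteomes.items():
        if label == config.reference:
            continue
        split = overlap_split(proteome, reference)
        membership = pd.DataFrame(
            {
                "protein_id": proteome.ids,
                "group": [
                    "overlap" if pid in split.overlap_ids else "unique"
                    for pid in proteome.ids
                ],
            }
        )
        outputs[f"{label}_membership"] = _write(
            membership, out_dir / f"{label}_overlap.tsv"
        )
        if split.n_overlap < 2 or split.n_unique < 2:
            log.skip(label, "overlap statistics skipped: a membership group has < 2 proteins")
            continue
        groups = _metric_groups(
            {
                "overlap": Proteome("overlap", [proteome[p] for p in sorted(split.overlap_ids)]),
                "unique": Proteome("unique", [proteome[p] for p in sorted(split.unique_ids)]),
            },
            predictor,
            config.llps,
        )
        for metric, per_label in groups.items():
            vectors = [per_label["overlap"], per_label["unique"]]
            if any(len(v) < 2 for v in vectors):
                continue
            try:
                res = one_way_anova(vectors)
            except ValueError as err:
                log.skip(label, f"{metric} ANOVA skipped: {err}")
                continue
            stat_rows.append((label, metric, res.f_stat, res.p_value))
    outputs["overlap_anova"] = _write(
        pd.DataFrame(stat_rows, columns=["proteome", "metric", "F", "p"]),
        out_dir / "overlap_anova.tsv",
    )
    log.write(out_dir / "run.log")
    outputs["run_log"] = out_dir / "run.log"
    return outputs


def run_simulate(
    n: int,
    mixture: Mapping[str, float],
    seed: int,
    out_dir: str | Path,
    name: str = "synthetic",
) -> dict[str, Path]:
    """Generate a synthetic proteome; write FASTA plus ground-truth labels."""
    try:
        arch_mixture = {Archetype(k): float(v) for k, v in mixture.items()}
        spec = SyntheticProteomeSpec(n, arch_mixture, seed)
    except ValueError as err:
        raise ConfigError(str(err)) from err
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome, labels = generate_proteome(spec, name)
    fasta = out_dir / f"{name}.fasta"
    write_fasta(proteome, fasta)
    labels_path = out_dir / f"{name}_labels.tsv"
    write_labels(labels, labels_path)
    return {"fasta": fasta, "labels": labels_path}
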