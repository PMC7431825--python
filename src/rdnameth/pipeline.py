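"""End-to-end drivers: simulation → read calling → ER → statistics → clock.

``run_dbs_study`` reproduces the deep-bisulfite study design in silico:
young (26–36 y) and old (43–60 y) donor cohorts of 23 samples each, for two
rDNA regions, with per-sample A- and G-allele read sets.  It returns a tidy
per-sample/per-allele summary table plus a cohort report with mean
methylation, mean epimutation rate, old/young ER fold changes and
Mann–Whitney p-values.

``run_clock_pipeline`` applies the clock workflow (QC → KNN imputation →
ElasticNet fit with 1-SE λ) to a training cohort and evaluates on both the
training and an independent test cohort.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .allele import allele_summary, split_by_allele
from .amplicon import AmpliconReference, call_reads, filter_reads, prepare_reference
from .clock import evaluate, fit_clock, knn_impute, predict_age, qc_filter_samples
from .cohort import er_ratio, group_compare
from .errors import PipelineError
from .presets import MixturePreset, builtin_presets
from .synthetic import make_reference, simulate_dbs_reads

__all__ = [
    "PipelineConfig",
    "process_sample",
    "process_fastq",
    "run_dbs_study",
    "dbs_cohort_report",
    "run_dbs_pipeline",
    "run_clock_pipeline",
    "write_table",
]

#: Age ranges of the two DBS donor classes (years).
AGE_RANGES = {"young": (26.0, 36.0), "old": (43.0, 60.0)}


@dataclass
class PipelineConfig:
    """Thresholds, sizes, and seeds for the end-to-end drivers."""

    out_dir: str = "results"
    n_samples: int = 23
    n_reads_per_allele: int = 5000
    conversion_failure: float = 0.005
    seq_error: float = 0.001
    conv_threshold: float = 0.95
    min_cpg_call_frac: float = 0.9
    max_missing: int = 9
    knn_k: int = 10
    alpha: float = 0.5
    n_folds: int = 10
    seed: int = 0
    dispersion_mode: str = "fixed"
    regions: tuple[str, ...] = ("region1", "region2")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @staticmethod
    def from_json(source: str | Path) -> "PipelineConfig":
        text = str(source)
        if "{" not in text:  # a path, not inline JSON
            text = Path(source).read_text()
        d = json.loads(text)
        d["regions"] = tuple(d.get("regions", ("region1", "region2")))
        return PipelineConfig(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None,
                index: bool = False) -> None:
    """Write a CSV with '#'-prefixed provenance comments above the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# rdnameth {__version__}\n")
        if config is not None:
            fh.write(f"# config_sha256={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, index=index)


def process_sample(
    ref: AmpliconReference,
    reads,
    read_ids=None,
    conv_threshold: float = 0.95,
    min_cpg_call_frac: float = 0.9,
):
    """Call → filter → allele-split → summarize one sample's reads.

    Returns (summaries by allele, qc tally).  ``reads`` is either a uint8
    read matrix or an iterable of (id, sequence) pairs.
    """
    annref = prepare_reference(ref)
    profiles, n_unaligned = call_reads(reads, annref, read_ids=read_ids)
    passing, tally = filter_reads(profiles, conv_threshold, min_cpg_call_frac)
    tally["unalignable"] = n_unaligned
    by_allele = split_by_allele(passing)
    summaries = {
        allele: allele_summary(p, allele) for allele, p in by_allele.items() if len(p)
    }
    return summaries, tally


def process_fastq(
    ref: AmpliconReference,
    fastq: str | Path,
    conv_threshold: float = 0.95,
    min_cpg_call_frac: float = 0.9,
):
    """File-based variant of :func:`process_sample`."""
    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fastq), "fastq")]
    if not pairs:
        raise PipelineError("call", str(fastq), "empty reads file")
    return process_sample(ref, pairs, None, conv_threshold, min_cpg_call_frac)


def run_dbs_study(
    config: PipelineConfig | None = None,
    presets: Mapping[tuple[str, str, str], MixturePreset] | None = None,
) -> pd.DataFrame:
    """Simulate and process the full young/old two-region DBS study.

    One row per (region, age class, sample, allele) with read counts, mean
    methylation (%) and epimutation rate (%).  Deterministic given
    ``config.seed``.
    """
    config = config or PipelineConfig()
    presets = presets or builtin_presets(config.dispersion_mode)
    rows = []
    for ri, region in enumerate(config.regions):
        ref = make_reference(region)
        for ai, age_class in enumerate(("young", "old")):
            preset_a = presets[(region, "A", age_class)]
            preset_g = presets[(region, "G", age_class)]
            for s in range(config.n_samples):
                # deterministic per-sample stream: seed + (cohort, sample) key
                child = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(2 * ri + ai, s)
                    )
                )
                sample_id = f"{region}_{age_class}_{s + 1:02d}"
                reads, ids, _truth = simulate_dbs_reads(
                    ref,
                    preset_a,
                    preset_g,
                    config.n_reads_per_allele,
                    conversion_failure=config.conversion_failure,
                    seq_error=config.seq_error,
                    seed=child,
                    sample_id=sample_id,
                )
                try:
                    summaries, _tally = process_sample(
                        ref, reads, ids, config.conv_threshold, config.min_cpg_call_frac
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    raise PipelineError("process_sample", sample_id, str(exc)) from exc
                for allele, summ in summaries.items():
                    rows.append(
                        {
                            "region": region,
                            "age_class": age_class,
                            "sample_id": sample_id,
                            "allele": allele,
                            "n_reads": summ.n_reads,
                            "mean_methylation": summ.mean_methylation,
                            "epimutation_rate": summ.epimutation_rate,
                        }
                    )
    return pd.DataFrame(rows)


def dbs_cohort_report(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the per-sample table into cohort statistics.

    Cohort means are unweighted means over samples (not pooled reads).  For
    each (region, allele) the old/young ER fold change and a Mann–Whitney
    p-value are reported; for each region × age class, the A/G ER ratio.
    """
    rows = []
    for (region, allele), grp in per_sample.groupby(["region", "allele"]):
        young = grp[grp.age_class == "young"]
        old = grp[grp.age_class == "old"]
        for age_class, sub in (("young", young), ("old", old)):
            rows.append(
                {
                    "region": region,
                    "allele": allele,
                    "age_class": age_class,
                    "n_samples": len(sub),
                    "mean_methylation": sub.mean_methylation.mean(),
                    "sd_methylation": sub.mean_methylation.std(ddof=1),
                    "mean_er": sub.epimutation_rate.mean(),
                    "sd_er": sub.epimutation_rate.std(ddof=1),
                }
            )
        if len(young) and len(old):
            ratio = er_ratio(old.epimutation_rate, young.epimutation_rate)
            _, p = group_compare(
                old.epimutation_rate, young.epimutation_rate, test="mannwhitney"
            )
            rows[-1]["er_ratio_old_young"] = ratio
            rows[-1]["er_mw_p"] = p
    report = pd.DataFrame(rows)

    # A/G ER ratio within each region × age class
    ag = []
    for (region, age_class), grp in per_sample.groupby(["region", "age_class"]):
        a = grp[grp.allele == "A"].epimutation_rate
        g = grp[grp.allele == "G"].epimutation_rate
        if len(a) and len(g) and g.mean() > 0:
            ag.append(
                {
                    "region": region,
                    "age_class": age_class,
                    "er_ratio_a_g": er_ratio(a, g),
                }
            )
    report.attrs["a_vs_g"] = pd.DataFrame(ag)
    return report


def run_dbs_pipeline(config: PipelineConfig | None = None) -> dict[str, pd.DataFrame]:
    """Full DBS driver: simulate, process, aggregate, write outputs.

    Writes ``dbs_per_sample.csv`` and ``dbs_cohort_report.csv`` (plus the
    A-vs-G ratio table) under ``config.out_dir`` with provenance headers.
    """
    config = config or PipelineConfig()
    per_sample = run_dbs_study(config)
    report = dbs_cohort_report(per_sample)
    out = Path(config.out_dir)
    write_table(per_sample, out / "dbs_per_sample.csv", config)
    write_table(report, out / "dbs_cohort_report.csv", config)
    write_table(report.attrs["a_vs_g"], out / "dbs_a_vs_g.csv", config)
    return {"per_sample": per_sample, "report": report, "a_vs_g": report.attrs["a_vs_g"]}


def run_clock_pipeline(
    train_matrix: pd.DataFrame,
    train_ages,
    test_matrix: pd.DataFrame | None = None,
    test_ages=None,
    config: PipelineConfig | None = None,
) -> dict:
    """QC → impute → fit on the training cohort; evaluate on train and test.

    Raises a leakage error when train and test share sample ids.  Returns a
    dict with the model, per-cohort metrics, and predictions; writes
    ``clock_model.json`` and ``clock_metrics.csv`` when ``config.out_dir``
    is set.
    """
    config = config or PipelineConfig()
    if test_matrix is not None:
        overlap = set(train_matrix.index) & set(test_matrix.index)
        if overlap:
            raise PipelineError(
                "clock", None, f"train/test sample overlap: {sorted(overlap)[:5]}"
            )

    train_ages = pd.Series(np.asarray(train_ages, float), index=train_matrix.index)
    kept, dropped = qc_filter_samples(train_matrix, config.max_missing)
    imputed = knn_impute(kept, k=min(config.knn_k, len(kept) - 1))
    model, cv = fit_clock(
        imputed,
        train_ages.loc[imputed.index],
        alpha=config.alpha,
        n_folds=config.n_folds,
        seed=config.seed,
    )
    pred_train = predict_age(model, imputed)
    metrics = {"train": evaluate(pred_train, train_ages.loc[imputed.index])}
    predictions = {"train": pred_train}

    if test_matrix is not None:
        test_ages = pd.Series(np.asarray(test_ages, float), index=test_matrix.index)
        kept_t, _ = qc_filter_samples(test_matrix, config.max_missing)
        imputed_t = knn_impute(kept_t, k=min(config.knn_k, len(kept_t) - 1))
        pred_test = predict_age(model, imputed_t)
        metrics["test"] = evaluate(pred_test, test_ages.loc[imputed_t.index])
        predictions["test"] = pred_test

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.to_json(out / "clock_model.json")
    mrows = pd.DataFrame(
        [
            {"cohort": name, "mse": m.mse, "mad": m.mad, "r": m.r}
            for name, m in metrics.items()
        ]
    )
    write_table(mrows, out / "clock_metrics.csv", config)
    return {
        "model": model,
        "metrics": metrics,
        "predictions": predictions,
        "cv_curve": cv,
        "dropped_train": dropped,
    }
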