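"""Calibrated presets for the single-molecule and cohort simulators.

The deep-bisulfite-sequencing (DBS) simulator models each sperm DNA molecule
as coming from a two-component mixture: a large background population with a
low per-CpG methylation probability, plus a small fraction of fully
hypermethylated molecules (epigenetically silenced rDNA units).  A preset
pins down that mixture so that the *population* mean methylation and the
expected epimutation rate (fraction of molecules with >50% methylated CpGs)
equal published cohort summary values for young and old sperm donors.

Cohort presets describe bulk (pyrosequencing-style) sample-by-CpG matrices
in which regional methylation increases linearly with donor age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.stats import binom

from .errors import InvalidPresetError

__all__ = [
    "MixturePreset",
    "CohortSpec",
    "derive_mixture_preset",
    "builtin_preset",
    "builtin_presets",
    "cohort_preset",
    "DBS_REGIONS",
    "SPERM_DBS_SUMMARY",
    "COHORT_PRESETS",
]

#: CpGs per DBS amplicon region: region1 covers the external transcribed
#: spacer (38 CpGs), region2 the UCE + core promoter (25 CpGs).
DBS_REGIONS: Mapping[str, int] = {"region1": 38, "region2": 25}

#: Empirical sperm-cohort summaries the DBS simulator is calibrated to:
#: (region, variant, age_class) -> (n_samples, meth_mean_pct, meth_sd_pct,
#: er_mean_pct, er_sd_pct).  Young donors are 26-36 y, old donors 43-60 y.
SPERM_DBS_SUMMARY: Mapping[tuple[str, str, str], tuple[int, float, float, float, float]] = {
    ("region1", "A", "young"): (23, 7.92, 1.24, 0.32, 0.75),
    ("region1", "A", "old"): (23, 14.75, 2.53, 1.36, 1.45),
    ("region1", "G", "young"): (23, 7.92, 1.22, 0.23, 0.49),
    ("region1", "G", "old"): (23, 14.80, 2.70, 1.00, 1.83),
    ("region2", "A", "young"): (22, 11.47, 2.95, 1.61, 1.96),
    ("region2", "A", "old"): (22, 23.70, 9.38, 9.52, 14.90),
    ("region2", "G", "young"): (23, 9.30, 1.19, 0.42, 0.66),
    ("region2", "G", "old"): (23, 18.24, 2.52, 2.30, 1.77),
}

#: Default per-CpG methylation probability of a hypermethylated molecule.
#: High enough that such molecules are unambiguously >50% methylated, while
#: keeping the background binomial tail above n/2 below 1e-4.
DEFAULT_P_HYPER = 0.85


@dataclass(frozen=True)
class MixturePreset:
    """Two-component molecule mixture for one (region, variant, age class).

    ``fixed`` dispersion mode draws every sample from the same mixture;
    ``dispersed`` mode jitters the per-sample target mean methylation and
    epimutation rate (mean-preserving, truncated to the feasible region) to
    emulate between-donor variation.
    """

    region: str
    variant: str
    age_class: str
    n_cpgs: int
    f_hyper: float
    p_hyper: float
    p_bg: float
    dispersion_mode: str = "fixed"
    sample_sd_meth: float = 0.0  # percentage points, dispersed mode only
    sample_sd_er: float = 0.0  # percentage points, dispersed mode only

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg <= self.p_hyper <= 1.0):
            raise InvalidPresetError(
                f"need 0 <= p_bg <= p_hyper <= 1, got p_bg={self.p_bg}, "
                f"p_hyper={self.p_hyper}"
            )
        if not (0.0 <= self.f_hyper <= 1.0):
            raise InvalidPresetError(f"f_hyper out of [0,1]: {self.f_hyper}")
        if self.n_cpgs < 1:
            raise InvalidPresetError(f"n_cpgs must be >= 1, got {self.n_cpgs}")
        if self.dispersion_mode not in ("fixed", "dispersed"):
            raise InvalidPresetError(f"unknown dispersion_mode {self.dispersion_mode!r}")

    @property
    def target_mean_meth(self) -> float:
        """Population mean methylation in % implied by the mixture."""
        return 100.0 * (self.f_hyper * self.p_hyper + (1.0 - self.f_hyper) * self.p_bg)

    @property
    def expected_er(self) -> float:
        """Expected epimutation rate in % (≈ 100·f_hyper when the background
        tail is negligible)."""
        return 100.0 * self.f_hyper

    def background_tail(self) -> float:
        """P(Binomial(n_cpgs, p_bg) > n_cpgs/2): chance a *background*
        molecule crosses the hypermethylation threshold."""
        return float(binom.sf(self.n_cpgs // 2, self.n_cpgs, self.p_bg))

    def with_targets(self, mean_meth: float, er: float) -> "MixturePreset":
        """Re-derive the mixture for new (mean %, ER %) targets, keeping
        p_hyper and metadata."""
        d = derive_mixture_preset(mean_meth, er, self.p_hyper, self.n_cpgs)
        return replace(self, f_hyper=d.f_hyper, p_bg=d.p_bg)


def derive_mixture_preset(
    target_mean_meth: float,
    target_er: float,
    p_hyper: float = DEFAULT_P_HYPER,
    n_cpgs: int = 38,
    *,
    region: str = "custom",
    variant: str = "A",
    age_class: str = "custom",
    **kwargs,
) -> MixturePreset:
    """Translate a printed (mean methylation %, epimutation rate %) pair into
    mixture parameters.

    The hypermethylated fraction is ``f_hyper = target_er/100`` and the
    background per-CpG probability solves the mean-reconstruction identity::

        f_hyper*p_hyper + (1 - f_hyper)*p_bg = target_mean_meth/100

    Raises
    ------
    InvalidPresetError
        If the targets are incompatible at the given p_hyper (p_bg would
        fall outside [0, p_hyper]) or target_er >= 100.
    """
    if not (0.0 < p_hyper <= 1.0):
        raise InvalidPresetError(f"p_hyper must be in (0, 1], got {p_hyper}")
    if not (0.0 <= target_er < 100.0):
        raise InvalidPresetError(f"target_er must be in [0, 100), got {target_er}")
    f_hyper = target_er / 100.0
    p_bg = (target_mean_meth / 100.0 - f_hyper * p_hyper) / (1.0 - f_hyper)
    # forgive floating-point dust at the feasibility boundary
    if -1e-12 < p_bg < 0.0:
        p_bg = 0.0
    elif p_hyper < p_bg < p_hyper + 1e-12:
        p_bg = p_hyper
    if p_bg < 0.0 or p_bg > p_hyper:
        raise InvalidPresetError(
            f"target mean {target_mean_meth}% incompatible with ER {target_er}% "
            f"at p_hyper={p_hyper} (implied p_bg={p_bg:.4f})"
        )
    return MixturePreset(
        region=region,
        variant=variant,
        age_class=age_class,
        n_cpgs=n_cpgs,
        f_hyper=f_hyper,
        p_hyper=p_hyper,
        p_bg=p_bg,
        **kwargs,
    )


def builtin_preset(
    region: str, variant: str, age_class: str, dispersion_mode: str = "fixed"
) -> MixturePreset:
    """Built-in preset for one empirical sperm-cohort row."""
    key = (region, variant, age_class)
    if key not in SPERM_DBS_SUMMARY:
        raise InvalidPresetError(f"no built-in preset for {key}")
    _, meth, meth_sd, er, er_sd = SPERM_DBS_SUMMARY[key]
    return derive_mixture_preset(
        meth,
        er,
        DEFAULT_P_HYPER,
        DBS_REGIONS[region],
        region=region,
        variant=variant,
        age_class=age_class,
        dispersion_mode=dispersion_mode,
        sample_sd_meth=meth_sd if dispersion_mode == "dispersed" else 0.0,
        sample_sd_er=er_sd if dispersion_mode == "dispersed" else 0.0,
    )


def builtin_presets(dispersion_mode: str = "fixed") -> dict[tuple[str, str, str], MixturePreset]:
    """All eight built-in (region, variant, age class) presets."""
    return {k: builtin_preset(*k, dispersion_mode) for k in SPERM_DBS_SUMMARY}


# ---------------------------------------------------------------------------
# Cohort-level (bulk) simulation
# ---------------------------------------------------------------------------

#: CpG counts of the four bulk rDNA amplicons (53 CpGs total).
BPS_AMPLICONS: Mapping[str, int] = {"UCE": 26, "promoter": 9, "18S": 8, "28S": 10}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a bulk methylation cohort with a linear age effect.

    Each cell is ``clip(baseline_j + slope*age_i + u_i + eps_ij, 0, 100)``
    with a per-sample offset u_i ~ N(0, sample_sd^2) and per-cell noise
    eps_ij ~ N(0, cpg_sd^2); cells go missing completely at random with
    probability ``missing_rate``.
    """

    n_samples: int
    age_low: float
    age_high: float
    slope: float  # percentage points of methylation per year of age
    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"UCE": 6.0, "promoter": 5.0, "18S": 4.0, "28S": 6.0}
    )
    amplicon_cpgs: Mapping[str, int] = field(default_factory=lambda: dict(BPS_AMPLICONS))
    sample_sd: float = 0.0
    cpg_sd: float = 0.0
    missing_rate: float = 0.0
    tissue: str = "sperm"
    species: str = "human"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise InvalidPresetError("cohort needs n_samples >= 3")
        if self.age_low <= 0 or self.age_high < self.age_low:
            raise InvalidPresetError("need 0 < age_low <= age_high")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidPresetError("missing_rate must be in [0, 1)")
        missing = set(self.baseline) ^ set(self.amplicon_cpgs)
        if missing:
            raise InvalidPresetError(f"baseline/amplicon mismatch for {sorted(missing)}")

    @property
    def cpg_ids(self) -> list[str]:
        """Column labels, amplicon by amplicon: e.g. promoter_1 ... promoter_9."""
        return [
            f"{amp}_{i + 1}"
            for amp, n in self.amplicon_cpgs.items()
            for i in range(n)
        ]

    def region_columns(self, amplicon: str) -> list[str]:
        return [f"{amplicon}_{i + 1}" for i in range(self.amplicon_cpgs[amplicon])]

    def baseline_vector(self) -> np.ndarray:
        return np.concatenate(
            [np.full(n, self.baseline[amp]) for amp, n in self.amplicon_cpgs.items()]
        )


#: Default aging cohorts.  Slopes are the published regional methylation
#: increments per year of age (human sperm 0.33 %/yr, human blood 0.06 %/yr);
#: cohort sizes and age ranges match the corresponding study cohorts.  The
#: age-0 baselines are simulator choices placing methylation in a realistic
#: low range clear of the [0, 100] clip.
COHORT_PRESETS: Mapping[str, CohortSpec] = {
    "human_sperm": CohortSpec(
        n_samples=186,
        age_low=25.0,
        age_high=66.0,
        slope=0.33,
        sample_sd=2.0,
        cpg_sd=1.5,
        tissue="sperm",
    ),
    "human_blood": CohortSpec(
        n_samples=188,
        age_low=1.0,
        age_high=70.0,
        slope=0.06,
        baseline={"UCE": 12.0, "promoter": 10.0, "18S": 8.0, "28S": 12.0},
        sample_sd=2.0,
        cpg_sd=1.5,
        tissue="blood",
    ),
}


def cohort_preset(name: str, **overrides) -> CohortSpec:
    """Fetch a named cohort preset, optionally overriding fields."""
    if name not in COHORT_PRESETS:
        raise InvalidPresetError(f"unknown cohort preset {name!r}")
    return replace(COHORT_PRESETS[name], **overrides) if overrides else COHORT_PRESETS[name]
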