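"""Allele-specific aggregation and the epimutation-rate statistic.

An *epimutation* is a single DNA molecule (one sequencing read) on which more
than half of the called CpGs are methylated — such rDNA units are considered
epigenetically silenced.  The epimutation rate (ER) of a read set is the
percentage of reads that are hypermethylated in this sense; reads at exactly
50% do not count (the threshold is strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amplicon import MISSING, METHYLATED, ReadMethylationProfile, ReadProfiles
from .errors import UndefinedStatisticError

__all__ = [
    "AlleleSummary",
    "split_by_allele",
    "read_methylation_fraction",
    "methylation_fractions",
    "epimutation_rate",
    "allele_summary",
]

HYPERMETHYLATION_CUTOFF = 0.5


@dataclass
class AlleleSummary:
    """Per-allele aggregate over one sample's passing reads."""

    allele: str
    n_reads: int
    mean_methylation: float  # % (mean over reads of per-read fraction × 100)
    per_cpg_mean: np.ndarray  # % per CpG; NaN where no calls
    n_hypermethylated: int
    epimutation_rate: float  # %


def split_by_allele(profiles: ReadProfiles) -> dict[str, ReadProfiles]:
    """Partition passing reads by their A/G allele call."""
    return {allele: profiles.subset(profiles.alleles == allele) for allele in ("A", "G")}


def read_methylation_fraction(profile: ReadMethylationProfile) -> float:
    """Fraction of *called* (non-missing) CpGs that are methylated."""
    called = profile.cpg_calls != MISSING
    if not called.any():
        raise UndefinedStatisticError(f"read {profile.read_id}: no called CpGs")
    return float((profile.cpg_calls[called] == METHYLATED).mean())


def methylation_fractions(profiles: ReadProfiles) -> np.ndarray:
    """Vectorized per-read methylation fractions."""
    called = (profiles.calls != MISSING).sum(axis=1)
    if (called == 0).any():
        bad = profiles.read_ids[called == 0][:3]
        raise UndefinedStatisticError(f"reads with no called CpGs, e.g. {list(bad)}")
    meth = (profiles.calls == METHYLATED).sum(axis=1)
    return meth / called


def epimutation_rate(profiles: ReadProfiles) -> float:
    """100 × (reads with methylation fraction strictly > 0.5) / total reads."""
    if len(profiles) == 0:
        raise UndefinedStatisticError("epimutation rate undefined for empty read set")
    frac = methylation_fractions(profiles)
    return 100.0 * float((frac > HYPERMETHYLATION_CUTOFF).mean())


def allele_summary(profiles: ReadProfiles, allele: str | None = None) -> AlleleSummary:
    """Aggregate one allele's reads: mean methylation, per-CpG means, ER.

    Per-CpG means are over non-missing calls; a CpG with zero calls is NaN
    (flagged missing), never silently zero.
    """
    if len(profiles) == 0:
        raise UndefinedStatisticError("cannot summarize an empty read set")
    if allele is None:
        uniq = set(profiles.alleles.tolist())
        allele = uniq.pop() if len(uniq) == 1 else "mixed"

    frac = methylation_fractions(profiles)
    called = profiles.calls != MISSING
    meth = profiles.calls == METHYLATED
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_cpg = np.where(
            n_called > 0, 100.0 * meth.sum(axis=0) / np.maximum(n_called, 1), np.nan
        )
    n_hyper = int((frac > HYPERMETHYLATION_CUTOFF).sum())
    return AlleleSummary(
        allele=allele,
        n_reads=len(profiles),
        mean_methylation=100.0 * float(frac.mean()),
        per_cpg_mean=per_cpg,
        n_hypermethylated=n_hyper,
        epimutation_rate=100.0 * n_hyper / len(profiles),
    )
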