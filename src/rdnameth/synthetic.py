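"""Synthetic single-molecule reads and bulk cohorts with known ground truth.

Two generators:

* ``simulate_dbs_reads`` emits bisulfite amplicon reads, one per simulated
  sperm DNA molecule.  Each molecule's per-CpG methylation is drawn from a
  two-component mixture (:class:`~rdnameth.presets.MixturePreset`), the
  molecule carries an A or G base at the amplicon's variant position, and the
  sequence then passes through an in-silico bisulfite conversion (unmethylated
  C → T, with a small per-site failure probability) and a substitution-error
  channel.  Reads are single-end, full-amplicon, top strand only.

* ``simulate_bps_cohort`` emits a sample × CpG β-value matrix (in %) whose
  regional methylation increases linearly with donor age, plus sample-level
  and per-cell Gaussian noise and optional missingness — the structure a bulk
  bisulfite (pyrosequencing-style) aging cohort is assumed to have.

Every generator returns a :class:`SimulationTruth` alongside its output, so
downstream calling and statistics can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconReference, _A, _C, _G, _T
from .errors import CohortTooSmallError, InvalidPresetError, ReferenceSpecError
from .presets import CohortSpec, MixturePreset

__all__ = [
    "SimulationTruth",
    "make_reference",
    "simulate_molecules",
    "simulate_dbs_reads",
    "reads_to_fastq",
    "simulate_bps_cohort",
]

_FILLERS = ("CAT", "TCA", "ACT", "CTA")  # each holds one non-CpG cytosine... almost
_QUAL = 37  # constant Phred quality for simulated bases


@dataclass
class SimulationTruth:
    """Ground truth emitted next to simulated data.

    For read sets: per-read methylation vectors, allele, hypermethylation
    flag, and conversion-failure counts.  For cohorts: true ages and the
    noise-free β matrix.  Round-trips through CSV.
    """

    reads: pd.DataFrame | None = None
    methylation: np.ndarray | None = None  # (n_reads, n_cpgs) bool
    cells: pd.DataFrame | None = None  # noise-free cohort β values
    ages: pd.Series | None = None

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        if self.reads is not None:
            df = self.reads.copy()
            df["methylation"] = [
                "".join("1" if m else "0" for m in row) for row in self.methylation
            ]
            df.to_csv(path / "truth_reads.csv", index=False)
        if self.cells is not None:
            self.cells.to_csv(path / "truth_cells.csv")
        if self.ages is not None:
            self.ages.rename("age").to_csv(path / "truth_ages.csv")

    @staticmethod
    def from_dir(path: str | Path) -> "SimulationTruth":
        path = Path(path)
        truth = SimulationTruth()
        if (path / "truth_reads.csv").exists():
            df = pd.read_csv(path / "truth_reads.csv", dtype={"methylation": str})
            truth.methylation = np.array(
                [[c == "1" for c in s] for s in df.pop("methylation")], dtype=bool
            )
            truth.reads = df
        if (path / "truth_cells.csv").exists():
            truth.cells = pd.read_csv(path / "truth_cells.csv", index_col=0)
        if (path / "truth_ages.csv").exists():
            truth.ages = pd.read_csv(path / "truth_ages.csv", index_col=0)["age"]
        return truth


def make_reference(region: str = "region1", n_cpgs: int | None = None,
                   name: str | None = None) -> AmpliconReference:
    """Construct a synthetic amplicon reference with ``n_cpgs`` CpGs, one
    A/G variant site, and one non-CpG cytosine per CpG block (QC sites).

    Deterministic: the sequence is built from fixed filler blocks, so the
    same arguments always give the same reference.  The default CpG counts
    follow the two DBS regions (38 and 25 CpGs).
    """
    from .presets import DBS_REGIONS

    if n_cpgs is None:
        if region not in DBS_REGIONS:
            raise ReferenceSpecError(f"unknown region {region!r}; give n_cpgs explicitly")
        n_cpgs = DBS_REGIONS[region]
    if n_cpgs < 1:
        raise ReferenceSpecError("need at least one CpG")

    parts: list[str] = ["ATTGA"]
    pos = len(parts[0])
    cpg_positions: list[int] = []
    variant_position = -1
    for i in range(n_cpgs):
        if i == n_cpgs // 2:
            block = "AATATA"  # reference shows the A allele at the variant site
            variant_position = pos + 3
            parts.append(block)
            pos += len(block)
        filler = _FILLERS[i % len(_FILLERS)]
        parts.append(filler)
        pos += len(filler)
        cpg_positions.append(pos)
        parts.append("CG")
        pos += 2
    parts.append("ATTA")
    return AmpliconReference(
        name=name or f"{region}_synthetic",
        region=region,
        sequence="".join(parts),
        cpg_positions=tuple(cpg_positions),
        variant_position=variant_position,
    )


def _sample_preset(preset: MixturePreset, rng: np.random.Generator) -> MixturePreset:
    """Draw a per-sample mixture in dispersed mode (identity in fixed mode)."""
    if preset.dispersion_mode != "dispersed":
        return preset
    for _ in range(100):
        mean = rng.normal(preset.target_mean_meth, preset.sample_sd_meth)
        er = max(0.0, rng.normal(preset.expected_er, preset.sample_sd_er))
        try:
            return preset.with_targets(mean, er)
        except InvalidPresetError:
            continue
    raise InvalidPresetError("could not draw a feasible dispersed sample preset")


def simulate_molecules(
    preset: MixturePreset, n_molecules: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, SimulationTruth]:
    """Draw binary methylation states for ``n_molecules`` molecules.

    Each molecule is hypermethylated with probability ``f_hyper``; its CpG
    states are then independent Bernoulli(p_hyper) or Bernoulli(p_bg).
    """
    if n_molecules < 1:
        raise InvalidPresetError("n_molecules must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hyper = rng.random(n_molecules) < preset.f_hyper
    p = np.where(hyper, preset.p_hyper, preset.p_bg)[:, None]
    meth = rng.random((n_molecules, preset.n_cpgs)) < p
    truth = SimulationTruth(
        reads=pd.DataFrame({"molecule": np.arange(n_molecules), "hyper": hyper}),
        methylation=meth,
    )
    return meth, truth


def _molecules_to_reads(
    ref: AmpliconReference,
    meth: np.ndarray,
    allele: str,
    conversion_failure: float,
    seq_error: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render molecules as read sequences (uint8 matrix); returns
    (reads, n_conversion_failures per read)."""
    template = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    n = len(meth)
    reads = np.tile(template, (n, 1))
    reads[:, ref.variant_position] = ord(allele)

    cpg = np.asarray(ref.cpg_positions, dtype=np.intp)
    all_c = np.flatnonzero(template == _C)
    noncpg = all_c[~np.isin(all_c, cpg)]

    # Bisulfite conversion: every unmethylated/non-CpG C -> T unless the
    # per-site conversion fails (stays C).
    fail_cpg = rng.random((n, len(cpg))) < conversion_failure
    fail_non = rng.random((n, len(noncpg))) < conversion_failure
    cpg_block = np.where(meth | fail_cpg, _C, _T).astype(np.uint8)
    reads[:, cpg] = cpg_block
    reads[:, noncpg] = np.where(fail_non, _C, _T).astype(np.uint8)

    if seq_error > 0:
        err = rng.random(reads.shape) < seq_error
        # substitute with one of the three other bases, uniformly
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(bases, reads[err])
        shift = rng.integers(1, 4, size=err.sum())
        reads[err] = bases[(idx + shift) % 4]

    return reads, fail_non.sum(axis=1) + (fail_cpg & ~meth).sum(axis=1)


def simulate_dbs_reads(
    ref: AmpliconReference,
    preset_a: MixturePreset,
    preset_g: MixturePreset,
    n_reads_per_allele: int,
    conversion_failure: float = 0.0,
    seq_error: float = 0.0,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Simulate one sample's deep-bisulfite read set for both alleles.

    Returns ``(reads, read_ids, truth)`` where ``reads`` is a uint8 matrix
    (2·n_reads_per_allele × amplicon length) and read ids encode the truth
    record (sample, allele, molecule index).
    """
    if not (0.0 <= conversion_failure < 1.0 and 0.0 <= seq_error < 1.0):
        raise InvalidPresetError("probabilities must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    blocks, ids, truth_rows, meth_all = [], [], [], []
    for allele, preset in (("A", preset_a), ("G", preset_g)):
        sp = _sample_preset(preset, rng)
        meth, mtruth = simulate_molecules(sp, n_reads_per_allele, rng)
        reads, n_fail = _molecules_to_reads(
            ref, meth, allele, conversion_failure, seq_error, rng
        )
        blocks.append(reads)
        ids.extend(
            f"{sample_id}:{allele}:{i}" for i in range(n_reads_per_allele)
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "read_id": ids[-n_reads_per_allele:],
                    "allele": allele,
                    "hyper": mtruth.reads["hyper"].to_numpy(),
                    "n_conversion_failures": n_fail,
                }
            )
        )
        meth_all.append(meth)

    truth = SimulationTruth(
        reads=pd.concat(truth_rows, ignore_index=True),
        methylation=np.vstack(meth_all),
    )
    return np.vstack(blocks), np.asarray(ids, dtype=object), truth


def reads_to_fastq(
    reads: np.ndarray, read_ids: np.ndarray, path: str | Path
) -> None:
    """Write a simulated read matrix as FASTQ (constant Q37 qualities)."""
    records = (
        SeqRecord(
            Seq(row.tobytes().decode()),
            id=str(rid),
            description="",
            letter_annotations={"phred_quality": [_QUAL] * len(row)},
        )
        for row, rid in zip(reads, read_ids)
    )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def simulate_bps_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate a bulk cohort: (β matrix %, sample metadata, truth).

    β_ij = clip(baseline_j + slope·age_i + u_i + ε_ij, 0, 100); covariates
    (BMI, sperm concentration) are drawn independently of age.
    """
    if spec.n_samples < 3:
        raise CohortTooSmallError("need at least 3 samples")
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = spec.n_samples
    ids = [f"{spec.tissue[:2].upper()}{i + 1:04d}" for i in range(n)]
    ages = rng.uniform(spec.age_low, spec.age_high, n)
    baseline = spec.baseline_vector()
    clean = baseline[None, :] + spec.slope * ages[:, None]

    u = rng.normal(0.0, spec.sample_sd, n) if spec.sample_sd > 0 else np.zeros(n)
    eps = (
        rng.normal(0.0, spec.cpg_sd, clean.shape)
        if spec.cpg_sd > 0
        else np.zeros_like(clean)
    )
    beta = np.clip(clean + u[:, None] + eps, 0.0, 100.0)

    matrix = pd.DataFrame(beta, index=ids, columns=spec.cpg_ids)
    if spec.missing_rate > 0:
        mask = rng.random(beta.shape) < spec.missing_rate
        matrix = matrix.mask(mask)

    bmi = np.clip(rng.normal(26.0, 4.0, n), 17.0, 40.0)
    sperm_conc = np.clip(rng.lognormal(np.log(40.0), 0.9, n), 0.2, 200.0)
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "age": ages,
            "bmi": bmi,
            "sperm_concentration": sperm_conc,
            "species": spec.species,
            "tissue": spec.tissue,
        }
    ).set_index("sample_id")

    truth = SimulationTruth(
        cells=pd.DataFrame(clean, index=ids, columns=spec.cpg_ids),
        ages=pd.Series(ages, index=ids, name="age"),
    )
    return matrix, meta, truth
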