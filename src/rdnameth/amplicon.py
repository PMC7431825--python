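"""Bisulfite amplicon read processing.

Turns raw bisulfite-converted amplicon reads into per-read methylation
profiles: a bisulfite-aware global alignment against the amplicon reference,
per-CpG methylation calls, an A/G allele call at the annotated variant
position, and a conversion-rate QC statistic computed from non-CpG cytosines
(which are assumed unmethylated in mammalian DNA, so any residual C there
marks a conversion failure).

Reads are then filtered with the study rules: a read is kept only if its
overall bisulfite conversion rate is strictly above 95%, enough of its CpGs
were callable, and its allele could be determined.

Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ReferenceSpecError

__all__ = [
    "AmpliconReference",
    "AnnotatedReference",
    "Alignment",
    "ReadMethylationProfile",
    "ReadProfiles",
    "prepare_reference",
    "align_read",
    "call_read_profile",
    "call_reads",
    "filter_reads",
    "load_reference",
]

# Methylation-call codes in the per-read CpG call matrix.
METHYLATED, UNMETHYLATED, MISSING = 1, 0, -1

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T, _A = (ord(x) for x in "CGTA")


@dataclass(frozen=True)
class AmpliconReference:
    """An amplicon reference sequence with CpG and A/G-variant annotation."""

    name: str
    region: str
    sequence: str
    cpg_positions: tuple[int, ...]
    variant_position: int
    variant_alleles: tuple[str, str] = ("A", "G")

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - set("ACGT"):
            raise ReferenceSpecError(f"{self.name}: sequence must be non-empty A/C/G/T")
        prev = -1
        for p in self.cpg_positions:
            if p <= prev:
                raise ReferenceSpecError(f"{self.name}: cpg_positions not strictly increasing at {p}")
            prev = p
            if p + 1 >= len(seq) or seq[p] != "C" or seq[p + 1] != "G":
                raise ReferenceSpecError(
                    f"{self.name}: position {p} is not the C of a CpG "
                    f"(context {seq[p:p + 2]!r})"
                )
        vp = self.variant_position
        if not (0 <= vp < len(seq)):
            raise ReferenceSpecError(f"{self.name}: variant_position {vp} out of range")
        if vp in self.cpg_positions or vp - 1 in self.cpg_positions:
            raise ReferenceSpecError(f"{self.name}: variant_position {vp} overlaps a CpG")
        if set(self.variant_alleles) != {"A", "G"}:
            raise ReferenceSpecError(f"{self.name}: variant alleles must be A/G")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "region": self.region,
            "cpg_positions": list(self.cpg_positions),
            "variant_position": self.variant_position,
            "variant_alleles": list(self.variant_alleles),
        }


@dataclass(frozen=True)
class AnnotatedReference:
    """Reference plus the partition of its cytosines into CpG / non-CpG sets."""

    ref: AmpliconReference
    cpg_positions: np.ndarray  # C of each CpG
    noncpg_c_positions: np.ndarray  # every other forward-strand C

    @property
    def sequence(self) -> str:
        return self.ref.sequence

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def seq_array(self) -> np.ndarray:
        return np.frombuffer(self.sequence.encode(), dtype=np.uint8)


def prepare_reference(ref: AmpliconReference) -> AnnotatedReference:
    """Validate a reference and index its CpG and non-CpG cytosines.

    Idempotent on the reference content; raises :class:`ReferenceSpecError`
    (from the dataclass validator) naming the offending position otherwise.
    """
    seq = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    all_c = np.flatnonzero(seq == _C)
    cpg = np.asarray(ref.cpg_positions, dtype=np.intp)
    noncpg = all_c[~np.isin(all_c, cpg)]
    return AnnotatedReference(ref=ref, cpg_positions=cpg, noncpg_c_positions=noncpg)


def load_reference(fasta: str | Path, annotation: str | Path) -> AmpliconReference:
    """Read a reference from FASTA plus a JSON annotation sidecar."""
    record = next(SeqIO.parse(str(fasta), "fasta"))
    meta = json.loads(Path(annotation).read_text())
    return AmpliconReference(
        name=meta.get("name", record.id),
        region=meta.get("region", ""),
        sequence=str(record.seq).upper(),
        cpg_positions=tuple(meta["cpg_positions"]),
        variant_position=meta["variant_position"],
        variant_alleles=tuple(meta.get("variant_alleles", ("A", "G"))),
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """Global alignment of one read against the reference.

    ``ref_to_read[j]`` is the read index aligned to reference position j, or
    -1 where the reference base is opposite a gap.
    """

    read: str
    score: float
    ref_to_read: np.ndarray
    aligned: bool = True


def _substitution_scores(read_arr: np.ndarray, ref_arr: np.ndarray,
                         match: float, mismatch: float) -> np.ndarray:
    """(len(read), len(ref)) substitution matrix; read T under reference C
    scores as a match (bisulfite asymmetry)."""
    eq = read_arr[:, None] == ref_arr[None, :]
    bis = (read_arr[:, None] == _T) & (ref_arr[None, :] == _C)
    return np.where(eq | bis, match, mismatch)


def align_read(
    read: str,
    annref: AnnotatedReference,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    score_floor: float | None = None,
) -> Alignment:
    """Bisulfite-aware Needleman–Wunsch global alignment.

    Ties in the traceback are broken deterministically: diagonal, then up
    (extra read base), then left (reference gap in the read).  If the score
    falls below ``score_floor`` (default ``0.5 * len(ref) * match``) the read
    is flagged unalignable rather than raising.
    """
    if not read:
        raise ValueError("empty read")
    ref_arr = annref.seq_array()
    read_arr = np.frombuffer(read.upper().encode(), dtype=np.uint8)
    n, m = len(read_arr), len(ref_arr)
    sub = _substitution_scores(read_arr, ref_arr, match, mismatch)

    S = np.empty((n + 1, m + 1))
    S[0, :] = gap * np.arange(m + 1)
    S[:, 0] = gap * np.arange(n + 1)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        best = np.maximum(S[i - 1, :-1] + sub[i - 1], S[i - 1, 1:] + gap)
        # Horizontal-gap closure: S[i,j] = max_k<=j (best[k] + gap*(j-k))
        run = np.maximum.accumulate(
            np.concatenate(([S[i, 0]], best)) - gap * js
        )
        S[i, 1:] = run[1:] + gap * js[1:]

    score = float(S[n, m])
    ref_to_read = np.full(m, -1, dtype=np.intp)
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(S[i, j], S[i - 1, j - 1] + sub[i - 1, j - 1]):
            ref_to_read[j - 1] = i - 1
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(S[i, j], S[i - 1, j] + gap):
            i -= 1
        else:
            j -= 1

    floor = 0.5 * m * match if score_floor is None else score_floor
    return Alignment(read=read.upper(), score=score, ref_to_read=ref_to_read,
                     aligned=score >= floor)


# ---------------------------------------------------------------------------
# Per-read calling
# ---------------------------------------------------------------------------


@dataclass
class ReadMethylationProfile:
    """One molecule's per-CpG calls, allele call, and conversion QC."""

    read_id: str
    allele: str  # "A", "G", or "undetermined"
    cpg_calls: np.ndarray  # int8 over reference CpGs: 1/0/-1
    n_noncpg_c_sites: int
    n_converted: int
    passed_qc: bool | None = None
    rejection_reason: str | None = None

    @property
    def conversion_rate(self) -> float:
        if self.n_noncpg_c_sites == 0:
            return float("nan")
        return self.n_converted / self.n_noncpg_c_sites

    @property
    def n_called_cpgs(self) -> int:
        return int((self.cpg_calls != MISSING).sum())


@dataclass
class ReadProfiles:
    """Column-oriented batch of read profiles (the pipeline workhorse).

    Scalar per-read fields live in flat arrays; ``calls`` is an
    (n_reads, n_cpgs) int8 matrix with codes 1 (methylated), 0
    (unmethylated), -1 (missing).
    """

    read_ids: np.ndarray  # object/str array
    alleles: np.ndarray  # 'A'/'G'/'N' (N = undetermined)
    calls: np.ndarray
    n_noncpg_c_sites: np.ndarray
    n_converted: np.ndarray
    passed_qc: np.ndarray = field(default=None)  # type: ignore[assignment]
    rejection_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.read_ids)
        if self.passed_qc is None:
            self.passed_qc = np.zeros(n, dtype=bool)
        if self.rejection_reason is None:
            self.rejection_reason = np.full(n, "", dtype=object)

    def __len__(self) -> int:
        return len(self.read_ids)

    @property
    def n_cpgs(self) -> int:
        return self.calls.shape[1]

    @property
    def conversion_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_noncpg_c_sites > 0,
                self.n_converted / np.maximum(self.n_noncpg_c_sites, 1),
                np.nan,
            )

    def subset(self, mask: np.ndarray) -> "ReadProfiles":
        return ReadProfiles(
            read_ids=self.read_ids[mask],
            alleles=self.alleles[mask],
            calls=self.calls[mask],
            n_noncpg_c_sites=self.n_noncpg_c_sites[mask],
            n_converted=self.n_converted[mask],
            passed_qc=self.passed_qc[mask],
            rejection_reason=self.rejection_reason[mask],
        )

    def __iter__(self) -> Iterator[ReadMethylationProfile]:
        conv = self.conversion_rates  # noqa: F841  (forces validation)
        for i in range(len(self)):
            allele = self.alleles[i]
            yield ReadMethylationProfile(
                read_id=str(self.read_ids[i]),
                allele="undetermined" if allele == "N" else str(allele),
                cpg_calls=self.calls[i],
                n_noncpg_c_sites=int(self.n_noncpg_c_sites[i]),
                n_converted=int(self.n_converted[i]),
                passed_qc=bool(self.passed_qc[i]),
                rejection_reason=self.rejection_reason[i] or None,
            )

    @staticmethod
    def from_profiles(profiles: Sequence[ReadMethylationProfile]) -> "ReadProfiles":
        n = len(profiles)
        n_cpgs = len(profiles[0].cpg_calls) if n else 0
        calls = np.full((n, n_cpgs), MISSING, dtype=np.int8)
        ids = np.empty(n, dtype=object)
        alleles = np.empty(n, dtype="U1")
        sites = np.zeros(n, dtype=np.int64)
        conv = np.zeros(n, dtype=np.int64)
        for i, p in enumerate(profiles):
            ids[i] = p.read_id
            alleles[i] = "N" if p.allele == "undetermined" else p.allele
            calls[i] = p.cpg_calls
            sites[i] = p.n_noncpg_c_sites
            conv[i] = p.n_converted
        return ReadProfiles(ids, alleles, calls, sites, conv)


def call_read_profile(
    alignment: Alignment, annref: AnnotatedReference, read_id: str = ""
) -> ReadMethylationProfile:
    """Call one aligned read.

    At each reference CpG cytosine, a read C is methylated, a read T
    unmethylated, anything else (including a gap) missing.  At each non-CpG
    reference cytosine, read T counts as converted, read C as unconverted,
    and gaps/other bases are excluded from the conversion denominator.  The
    allele is the read base at the variant position if it is A or G.
    """
    read_arr = np.frombuffer(alignment.read.encode(), dtype=np.uint8)
    m2r = alignment.ref_to_read

    def bases_at(positions: np.ndarray) -> np.ndarray:
        idx = m2r[positions]
        out = np.zeros(len(positions), dtype=np.uint8)
        covered = idx >= 0
        out[covered] = read_arr[idx[covered]]
        return out

    cpg_bases = bases_at(annref.cpg_positions)
    calls = np.full(annref.n_cpgs, MISSING, dtype=np.int8)
    calls[cpg_bases == _C] = METHYLATED
    calls[cpg_bases == _T] = UNMETHYLATED

    qc_bases = bases_at(annref.noncpg_c_positions)
    n_conv = int((qc_bases == _T).sum())
    n_sites = n_conv + int((qc_bases == _C).sum())

    vidx = m2r[annref.ref.variant_position]
    vbase = chr(read_arr[vidx]) if vidx >= 0 else ""
    allele = vbase if vbase in ("A", "G") else "undetermined"

    return ReadMethylationProfile(
        read_id=read_id,
        allele=allele,
        cpg_calls=calls,
        n_noncpg_c_sites=n_sites,
        n_converted=n_conv,
    )


def call_reads(
    reads: Iterable[tuple[str, str]] | np.ndarray,
    annref: AnnotatedReference,
    read_ids: Sequence[str] | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    score_floor: float | None = None,
) -> tuple[ReadProfiles, int]:
    """Call a batch of reads; returns (profiles, n_unalignable).

    ``reads`` is either an iterable of (read_id, sequence) pairs or a uint8
    matrix of equal-length reads (with ``read_ids`` supplied separately).
    Reads whose length equals the reference are called through a vectorized
    identity-mapping path when their substitution-only score clears the
    floor — exact for amplicon reads without indels — and fall back to full
    Needleman–Wunsch otherwise.
    """
    ref_arr = annref.seq_array()
    m = len(ref_arr)
    floor = 0.5 * m * match if score_floor is None else score_floor

    if isinstance(reads, np.ndarray):
        mat = reads
        ids = np.asarray(
            read_ids if read_ids is not None else [f"read{i}" for i in range(len(mat))],
            dtype=object,
        )
        odd: list[tuple[str, str]] = []
    else:
        pairs = list(reads)
        same = [(rid, s) for rid, s in pairs if len(s) == m]
        odd = [(rid, s) for rid, s in pairs if len(s) != m]
        ids = np.asarray([rid for rid, _ in same], dtype=object)
        mat = np.zeros((len(same), m), dtype=np.uint8)
        for i, (_, s) in enumerate(same):
            mat[i] = np.frombuffer(s.upper().encode(), dtype=np.uint8)

    # Vectorized identity-mapping path for full-length reads.
    eq = mat == ref_arr[None, :]
    bis = (mat == _T) & (ref_arr[None, :] == _C)
    ok = eq | bis
    scores = ok.sum(axis=1) * match + (~ok).sum(axis=1) * mismatch
    fast = scores >= floor

    cpg_bases = mat[:, annref.cpg_positions]
    calls = np.full((len(mat), annref.n_cpgs), MISSING, dtype=np.int8)
    calls[cpg_bases == _C] = METHYLATED
    calls[cpg_bases == _T] = UNMETHYLATED

    qc = mat[:, annref.noncpg_c_positions]
    n_conv = (qc == _T).sum(axis=1)
    n_sites = n_conv + (qc == _C).sum(axis=1)

    vbase = mat[:, annref.ref.variant_position]
    alleles = np.full(len(mat), "N", dtype="U1")
    alleles[vbase == _A] = "A"
    alleles[vbase == _G] = "G"

    batch = ReadProfiles(
        read_ids=ids[fast],
        alleles=alleles[fast],
        calls=calls[fast],
        n_noncpg_c_sites=n_sites[fast].astype(np.int64),
        n_converted=n_conv[fast].astype(np.int64),
    )

    # Slow path: length mismatches and low-identity full-length reads.
    slow: list[ReadMethylationProfile] = []
    n_unaligned = 0
    slow_inputs = odd + [
        (str(ids[i]), mat[i].tobytes().decode()) for i in np.flatnonzero(~fast)
    ]
    for rid, seq in slow_inputs:
        aln = align_read(seq, annref, match, mismatch, gap, score_floor=floor)
        if not aln.aligned:
            n_unaligned += 1
            continue
        slow.append(call_read_profile(aln, annref, read_id=rid))

    if slow:
        extra = ReadProfiles.from_profiles(slow)
        batch = ReadProfiles(
            read_ids=np.concatenate([batch.read_ids, extra.read_ids]),
            alleles=np.concatenate([batch.alleles, extra.alleles]),
            calls=np.vstack([batch.calls, extra.calls]) if len(batch) else extra.calls,
            n_noncpg_c_sites=np.concatenate([batch.n_noncpg_c_sites, extra.n_noncpg_c_sites]),
            n_converted=np.concatenate([batch.n_converted, extra.n_converted]),
        )
    return batch, n_unaligned


def filter_reads(
    profiles: ReadProfiles,
    conv_threshold: float = 0.95,
    min_cpg_call_frac: float = 0.9,
) -> tuple[ReadProfiles, dict[str, int]]:
    """Apply the read QC rules; returns (passing profiles, rejection tally).

    A read passes only with conversion rate *strictly* above
    ``conv_threshold``, at least ``min_cpg_call_frac`` of reference CpGs
    called, and a determined A/G allele.  Reads failing several rules are
    tallied under the first applicable reason, in that order, so that
    ``passed + rejected = total``.
    """
    n = len(profiles)
    reasons = ("no_qc_sites", "low_conversion", "low_cpg_coverage", "undetermined_allele")
    tally = dict.fromkeys(reasons + ("passed",), 0)
    if n == 0:
        return profiles, tally

    has_sites = profiles.n_noncpg_c_sites > 0
    conv = profiles.conversion_rates
    conv_ok = has_sites & (np.nan_to_num(conv, nan=-1.0) > conv_threshold)
    called_frac = (profiles.calls != MISSING).mean(axis=1)
    cpg_ok = called_frac >= min_cpg_call_frac
    allele_ok = profiles.alleles != "N"

    reason = np.full(n, "", dtype=object)
    reason[~allele_ok] = "undetermined_allele"
    reason[~cpg_ok] = "low_cpg_coverage"
    reason[~conv_ok] = "low_conversion"
    reason[~has_sites] = "no_qc_sites"
    passed = conv_ok & cpg_ok & allele_ok

    profiles.passed_qc = passed
    profiles.rejection_reason = reason
    for r in reasons:
        tally[r] = int((reason == r).sum())
    tally["passed"] = int(passed.sum())
    return profiles.subset(passed), tally
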