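"""Domain types for spike-in qRT-PCR benchmarking.

The pipeline revolves around a handful of small value types:

* :class:`MiRNASpecies` / :class:`MiRNAPanel` — the synthetic miRNA panel
  (two pools, A and B, mixed at known ratios into the study samples).
* :class:`AssayRecord` / :class:`AssayCatalog` — one qPCR assay per target
  sequence on a platform.
* :class:`SpikeDesign` — ground truth: copies per reaction of every spiked
  miRNA in every sample.  Absent pairs mean zero copies.
* :class:`CtTable` — long-form Ct measurements keyed by
  (sample, replicate, assay), with ``NaN`` as the in-memory representation
  of the UNDETECTED sentinel ("Undetermined" in files).
* :class:`PlatformConfig` — detection threshold / cycle count / replicate
  detection rule for one platform profile.

Sequences are stored in the DNA alphabet (U -> T) so assay target sequences
and miRNA sequences compare directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "UNDETECTED",
    "MirspikeError",
    "ValidationError",
    "DuplicateKeyError",
    "AlphabetError",
    "UndefinedFoldChangeError",
    "UndefinedFractionError",
    "ZeroVarianceError",
    "ComparisonRefusedError",
    "normalize_sequence",
    "MiRNASpecies",
    "MiRNAPanel",
    "AssayRecord",
    "AssayCatalog",
    "SpikeDesign",
    "CtMeasurement",
    "CtTable",
    "PlatformConfig",
    "expected_delta_ct",
]

VALID_ALPHABET = frozenset("ACGTN")


class _Undetected:
    """Singleton sentinel for a reaction that produced no Ct."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNDETECTED"

    def __bool__(self) -> bool:
        return False


#: Sentinel for "no signal within the run" (file token: ``Undetermined``).
UNDETECTED = _Undetected()


class MirspikeError(Exception):
    """Base class for all package errors."""


class ValidationError(MirspikeError):
    """Input violates a documented invariant."""


class DuplicateKeyError(ValidationError):
    """Two records share a key that must be unique."""


class AlphabetError(ValidationError):
    """A sequence contains characters outside {A, C, G, U, T, N}."""


class UndefinedFoldChangeError(MirspikeError):
    """Fold change requested for a miRNA with zero copies in a sample."""


class UndefinedFractionError(MirspikeError):
    """A fraction with a zero denominator was requested."""


class ZeroVarianceError(MirspikeError):
    """A statistic is undefined because an input vector has zero variance."""


class ComparisonRefusedError(MirspikeError):
    """Too few shared observations to compare two platforms."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA to the DNA alphabet (U -> T).

    Raises :class:`AlphabetError` on any character outside {A,C,G,U,T,N}.
    Idempotent: normalizing a normalized sequence is a no-op.
    """
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise AlphabetError(f"invalid sequence characters {sorted(bad)} in {seq!r}")
    return s


@dataclass(frozen=True)
class MiRNASpecies:
    """One synthetic miRNA: miRBase-style id, sequence (5'->3'), pool label."""

    mirna_id: str
    sequence: str
    pool: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.pool not in ("A", "B"):
            raise ValidationError(f"pool must be 'A' or 'B', got {self.pool!r}")
        if not self.sequence:
            raise ValidationError(f"empty sequence for {self.mirna_id}")


class MiRNAPanel:
    """A panel of synthetic miRNAs split into pools A and B."""

    def __init__(self, species: Iterable[MiRNASpecies]):
        self.species: list[MiRNASpecies] = list(species)
        self._by_id: dict[str, MiRNASpecies] = {}
        for sp in self.species:
            if sp.mirna_id in self._by_id:
                raise DuplicateKeyError(f"duplicate miRNA id {sp.mirna_id!r} in panel")
            self._by_id[sp.mirna_id] = sp

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[MiRNASpecies]:
        return iter(self.species)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self._by_id

    def __getitem__(self, mirna_id: str) -> MiRNASpecies:
        return self._by_id[mirna_id]

    @property
    def ids(self) -> list[str]:
        return [sp.mirna_id for sp in self.species]

    def pool_counts(self) -> dict[str, int]:
        counts = {"A": 0, "B": 0}
        for sp in self.species:
            counts[sp.pool] += 1
        return counts

    def pool_members(self, pool: str) -> list[MiRNASpecies]:
        return [sp for sp in self.species if sp.pool == pool]


@dataclass(frozen=True)
class AssayRecord:
    """A platform assay and the mature miRNA sequence it targets."""

    assay_id: str
    platform_id: str
    target_mirna_id: str | None
    target_sequence: str

    def __post_init__(self) -> None:
        if not self.target_sequence:
            raise ValidationError(f"assay {self.assay_id}: empty target sequence")
        object.__setattr__(
            self, "target_sequence", normalize_sequence(self.target_sequence)
        )


class AssayCatalog:
    """All assays of one (or several) platforms, keyed by assay id."""

    def __init__(self, records: Iterable[AssayRecord]):
        self.records: list[AssayRecord] = list(records)
        self._by_id: dict[str, AssayRecord] = {}
        for rec in self.records:
            key = rec.assay_id
            if key in self._by_id:
                raise DuplicateKeyError(f"duplicate assay id {key!r} in catalog")
            self._by_id[key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssayRecord]:
        return iter(self.records)

    def __contains__(self, assay_id: str) -> bool:
        return assay_id in self._by_id

    def __getitem__(self, assay_id: str) -> AssayRecord:
        return self._by_id[assay_id]

    @property
    def assay_ids(self) -> list[str]:
        return [r.assay_id for r in self.records]

    def subset(self, assay_ids: Iterable[str]) -> "AssayCatalog":
        wanted = set(assay_ids)
        return AssayCatalog(r for r in self.records if r.assay_id in wanted)


class SpikeDesign:
    """Ground-truth copies per reaction: (sample, miRNA) -> copies.

    An absent pair means the miRNA is not in the sample (0 copies).  The
    expected log2 fold change of a miRNA between two samples with nonzero
    copies in both is ``log2(c_a / c_b)``.
    """

    def __init__(self, copies: Mapping[tuple[str, str], float]):
        self._copies: dict[tuple[str, str], float] = {}
        for (sample, mirna), c in copies.items():
            c = float(c)
            if c < 0 or not math.isfinite(c):
                raise ValidationError(
                    f"copies_per_reaction must be finite and >= 0, got {c} "
                    f"for ({sample}, {mirna})"
                )
            if c > 0:
                self._copies[(str(sample), str(mirna))] = c

    def copies(self, sample_id: str, mirna_id: str) -> float:
        return self._copies.get((sample_id, mirna_id), 0.0)

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _ in self._copies})

    def present_mirnas(self, sample_id: str) -> set[str]:
        return {m for (s, m) in self._copies if s == sample_id}

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self._copies.items()))

    def scaled(self, factor: float, rename: Mapping[str, str]) -> "SpikeDesign":
        """New design with copies scaled by ``factor`` for renamed samples.

        ``rename`` maps old sample ids to new ones; samples not listed are
        dropped.  Used to derive dilution-series points from a base sample.
        """
        out = {}
        for (s, m), c in self._copies.items():
            if s in rename:
                out[(rename[s], m)] = c * factor
        return SpikeDesign(out)

    def merged(self, other: "SpikeDesign") -> "SpikeDesign":
        out = dict(self._copies)
        for (s, m), c in other._copies.items():
            if (s, m) in out:
                raise DuplicateKeyError(f"designs overlap at ({s}, {m})")
            out[(s, m)] = c
        return SpikeDesign(out)


def expected_delta_ct(
    design: SpikeDesign, sample_a: str, sample_b: str, mirna_id: str
) -> float:
    """Design-implied ΔCt of ``mirna_id`` between two samples.

    ΔCt is reported as Ct(sample_b) − Ct(sample_a): a miRNA four-fold
    *higher* in ``sample_a`` amplifies two cycles *earlier* there, giving
    ΔCt = +2.  Numerically this equals ``log2(c_a / c_b)``.
    """
    c_a = design.copies(sample_a, mirna_id)
    c_b = design.copies(sample_b, mirna_id)
    if c_a <= 0 or c_b <= 0:
        raise UndefinedFoldChangeError(
            f"{mirna_id}: zero copies in {sample_a if c_a <= 0 else sample_b}; "
            "fold change undefined"
        )
    return math.log2(c_a / c_b)


class CtMeasurement(NamedTuple):
    """One well: (sample, replicate, assay) -> Ct or UNDETECTED."""

    sample_id: str
    replicate_id: str
    assay_id: str
    value: float | _Undetected


_CT_COLUMNS = ["sample_id", "replicate_id", "assay_id", "ct"]


class CtTable:
    """Long-form collection of Ct measurements.

    Backed by a :class:`pandas.DataFrame` with columns
    ``sample_id, replicate_id, assay_id, ct`` where ``ct`` is a float and
    ``NaN`` encodes the UNDETECTED sentinel.  At most one measurement per
    (sample, replicate, assay) key.
    """

    def __init__(self, df: pd.DataFrame, max_cycles: float = 40.0):
        missing = [c for c in _CT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"CtTable missing columns: {missing}")
        df = df.loc[:, _CT_COLUMNS].copy()
        for col in ("sample_id", "replicate_id", "assay_id"):
            df[col] = df[col].astype(str)
        df["ct"] = pd.to_numeric(df["ct"], errors="raise").astype(float)
        self.df = df.reset_index(drop=True)
        self.max_cycles = float(max_cycles)
        self.validate()

    def validate(self) -> None:
        dup = self.df.duplicated(subset=["sample_id", "replicate_id", "assay_id"])
        if dup.any():
            row = self.df.loc[dup.idxmax()]
            raise DuplicateKeyError(
                "duplicate measurement for key "
                f"({row.sample_id}, {row.replicate_id}, {row.assay_id})"
            )
        ct = self.df["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > self.max_cycles))
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"Ct value {ct.iloc[i]} at row {i} outside (0, {self.max_cycles}]"
            )

    @classmethod
    def from_measurements(
        cls, measurements: Iterable[CtMeasurement], max_cycles: float = 40.0
    ) -> "CtTable":
        rows = [
            (
                m.sample_id,
                m.replicate_id,
                m.assay_id,
                np.nan if m.value is UNDETECTED else float(m.value),
            )
            for m in measurements
        ]
        return cls(pd.DataFrame(rows, columns=_CT_COLUMNS), max_cycles=max_cycles)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[CtMeasurement]:
        for row in self.df.itertuples(index=False):
            value = UNDETECTED if np.isnan(row.ct) else float(row.ct)
            yield CtMeasurement(row.sample_id, row.replicate_id, row.assay_id, value)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    @property
    def assays(self) -> list[str]:
        return sorted(self.df["assay_id"].unique())

    def replicates(self, sample_id: str) -> list[str]:
        sub = self.df[self.df["sample_id"] == sample_id]
        return sorted(sub["replicate_id"].unique())

    def sample(self, sample_id: str) -> "CtTable":
        sub = self.df[self.df["sample_id"] == sample_id]
        if sub.empty:
            raise MirspikeError(f"unknown sample {sample_id!r}")
        return CtTable(sub, max_cycles=self.max_cycles)

    def pivot_replicates(self, sample_id: str) -> pd.DataFrame:
        """Wide view of one sample: rows = assays, columns = replicates."""
        sub = self.df[self.df["sample_id"] == sample_id]
        if sub.empty:
            raise MirspikeError(f"unknown sample {sample_id!r}")
        return sub.pivot(index="assay_id", columns="replicate_id", values="ct")

    def concat(self, other: "CtTable") -> "CtTable":
        return CtTable(
            pd.concat([self.df, other.df], ignore_index=True),
            max_cycles=max(self.max_cycles, other.max_cycles),
        )

    def equals(self, other: "CtTable") -> bool:
        a = self.df.sort_values(_CT_COLUMNS[:3]).reset_index(drop=True)
        b = other.df.sort_values(_CT_COLUMNS[:3]).reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class PlatformConfig:
    """Detection parameters of one platform profile.

    detection_threshold_ct
        Ct cutoff; a numeric Ct <= threshold counts as detected (inclusive:
        a threshold "of 38" is meant to admit Ct 38 itself).
    max_cycles
        Thermocycler run length; Ct values beyond it cannot occur.
    detection_rule
        ``any_replicate`` (used for false-positive counting) or
        ``all_replicates`` (used for "n detected" summaries and for the
        recovery inclusion rule).
    """

    detection_threshold_ct: float = 38.0
    max_cycles: float = 40.0
    detection_rule: str = "any_replicate"

    def __post_init__(self) -> None:
        if self.detection_threshold_ct > self.max_cycles:
            raise ValidationError("detection_threshold_ct must be <= max_cycles")
        if self.detection_rule not in ("any_replicate", "all_replicates"):
            raise ValidationError(f"unknown detection rule {self.detection_rule!r}")

    def with_rule(self, rule: str) -> "PlatformConfig":
        return replace(self, detection_rule=rule)
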