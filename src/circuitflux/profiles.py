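"""Strand-aware per-nucleotide profiles and unit conversions.

Transcript profiles are built from aligned short-fragment records and carry
an explicit units tag so that downstream operations can refuse to mix
arbitrary-unit and absolute-unit data.  All coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "UNIT_ARB_MRNA",
    "UNIT_ARB_FLUX",
    "UNIT_RNAP_PER_S_PER_PROMOTER",
    "UNIT_RNAP_PER_S_TOTAL",
    "UNIT_RIBOSOMES",
    "UNIT_RIBOSOMES_PER_MRNA",
    "StrandedProfile",
    "AlignedFragment",
    "FragmentArray",
    "CalibrationConstants",
    "build_transcript_profile",
    "compute_fpkm",
    "mrna_to_flux",
    "flux_to_absolute",
    "map_psites_center_weighted",
    "normalize_occupancy_absolute",
    "occupancy_per_transcript",
]

UNIT_ARB_MRNA = "arb_mrna"
UNIT_ARB_FLUX = "arb_flux"
UNIT_RNAP_PER_S_PER_PROMOTER = "rnap_per_s_per_promoter"
UNIT_RNAP_PER_S_TOTAL = "rnap_per_s_total"
UNIT_RIBOSOMES = "ribosomes"
UNIT_RIBOSOMES_PER_MRNA = "ribosomes_per_mrna"

VALID_UNITS = frozenset(
    {
        UNIT_ARB_MRNA,
        UNIT_ARB_FLUX,
        UNIT_RNAP_PER_S_PER_PROMOTER,
        UNIT_RNAP_PER_S_TOTAL,
        UNIT_RIBOSOMES,
        UNIT_RIBOSOMES_PER_MRNA,
    }
)

SENSE = "+"
ANTISENSE = "-"


class AlignedFragment(NamedTuple):
    """One mapped read interval (0-based, half-open)."""

    reference_id: str
    start: int
    end: int
    strand: str


class FragmentArray:
    """Column-oriented container of aligned fragments on one reference.

    Behaves like a sequence of :class:`AlignedFragment` but keeps starts,
    ends and strands as numpy arrays so bulk operations stay vectorized.
    """

    def __init__(self, reference_id: str, starts, ends, strands) -> None:
        self.reference_id = reference_id
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.sense = np.asarray(strands) == SENSE if not isinstance(
            strands, np.ndarray
        ) or strands.dtype != bool else strands
        if not (len(self.starts) == len(self.ends) == len(self.sense)):
            raise ValueError("column lengths differ")

    @classmethod
    def from_fragments(cls, fragments: "Sequence[AlignedFragment]") -> "FragmentArray":
        ref = fragments[0].reference_id if len(fragments) else "ref"
        return cls(
            ref,
            [f.start for f in fragments],
            [f.end for f in fragments],
            [f.strand for f in fragments],
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> AlignedFragment:
        return AlignedFragment(
            self.reference_id,
            int(self.starts[i]),
            int(self.ends[i]),
            SENSE if self.sense[i] else ANTISENSE,
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


@dataclass(frozen=True)
class CalibrationConstants:
    """Constants used to move between arbitrary and absolute units.

    Attributes
    ----------
    gamma : float
        mRNA degradation rate in s^-1.
    rpu_to_rnaps : float
        RNAP/s per promoter corresponding to 1 RPU.
    copy_ratio : float
        Circuit-plasmid to output-plasmid copy number ratio.
    powerlaw_coeff, powerlaw_exp : float
        Empirical calibration of arbitrary flux to per-promoter RNAP/s:
        J_abs = copy_ratio * rpu_to_rnaps * powerlaw_coeff * J_arb**powerlaw_exp.
    n_circuit_copies, n_output_copies : int
        Plasmid copy numbers of the circuit and output plasmids.
    total_active_ribosomes : float
        Total number of actively translating ribosomes per cell.
    """

    gamma: float = 0.0067
    rpu_to_rnaps: float = 0.019
    copy_ratio: float = 2.25
    powerlaw_coeff: float = 5.05e-5
    powerlaw_exp: float = 1.64
    n_circuit_copies: int = 9
    n_output_copies: int = 4
    total_active_ribosomes: float = 20000.0

    def __post_init__(self) -> None:
        for name in (
            "gamma",
            "rpu_to_rnaps",
            "copy_ratio",
            "powerlaw_coeff",
            "powerlaw_exp",
            "n_circuit_copies",
            "n_output_copies",
            "total_active_ribosomes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"CalibrationConstants.{name} must be > 0")

    @property
    def absolute_flux_coeff(self) -> float:
        """Coefficient of the arbitrary-to-absolute flux power law.

        Computed from its three factors, never hard-coded.
        """
        return self.copy_ratio * self.rpu_to_rnaps * self.powerlaw_coeff


@dataclass
class StrandedProfile:
    """Per-nucleotide nonnegative signal on one strand of a reference."""

    reference_id: str
    strand: str
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units tag {self.units!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be a 1-D array")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("profile values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "StrandedProfile":
        return StrandedProfile(
            self.reference_id, self.strand, values, units or self.units
        )

    def interval_mean(self, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("zero-length interval")
        if start < 0 or end > len(self.values):
            raise ValueError("interval out of profile bounds")
        return float(self.values[start:end].mean())


def _fragment_arrays(
    fragments: Sequence[AlignedFragment],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(fragments, FragmentArray):
        return fragments.starts, fragments.ends, fragments.sense
    starts = np.fromiter((f.start for f in fragments), dtype=np.int64, count=len(fragments))
    ends = np.fromiter((f.end for f in fragments), dtype=np.int64, count=len(fragments))
    sense = np.fromiter(
        (f.strand == SENSE for f in fragments), dtype=bool, count=len(fragments)
    )
    return starts, ends, sense


def _coverage(starts: np.ndarray, ends: np.ndarray, length: int) -> np.ndarray:
    diff = np.zeros(length + 1, dtype=float)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, ends, -1.0)
    return np.cumsum(diff[:-1])


def build_transcript_profile(
    fragments: Sequence[AlignedFragment],
    reference_length: int,
    masked_regions: Iterable[tuple[int, int]] = (),
    reference_id: str | None = None,
) -> tuple[StrandedProfile, StrandedProfile]:
    """Build per-strand transcript profiles from aligned fragments.

    Per-nucleotide coverage is divided by the total number of mapped
    nucleotides in the sample (after masking, across both strands) and
    multiplied by 1e9.  Fragments overlapping a masked region by one or
    more nucleotides are removed entirely.

    Returns
    -------
    (sense, antisense) : tuple of StrandedProfile
        Both profiles share the normalizer; units are ``arb_mrna``.
    """
    if not fragments:
        raise ValueError("no fragments supplied")
    if reference_id is None:
        reference_id = fragments[0].reference_id
    starts, ends, sense = _fragment_arrays(fragments)
    if starts.min() < 0 or ends.max() > reference_length or (starts >= ends).any():
        raise ValueError("fragment outside reference bounds or empty")

    keep = np.ones(len(starts), dtype=bool)
    for mstart, mend in masked_regions:
        keep &= ~((starts < mend) & (ends > mstart))
    starts, ends, sense = starts[keep], ends[keep], sense[keep]

    total_nt = int((ends - starts).sum())
    if total_nt == 0:
        raise ValueError("no fragments remain after masking; normalizer is zero")

    profiles = []
    for mask, strand in ((sense, SENSE), (~sense, ANTISENSE)):
        cov = _coverage(starts[mask], ends[mask], reference_length)
        profiles.append(
            StrandedProfile(reference_id, strand, cov / total_nt * 1e9, UNIT_ARB_MRNA)
        )
    return profiles[0], profiles[1]


def compute_fpkm(profile: StrandedProfile, gene: tuple[int, int]) -> float:
    """Average profile height over a gene interval."""
    start, end = gene
    return profile.interval_mean(start, end)


def mrna_to_flux(profile: StrandedProfile, gamma: float) -> StrandedProfile:
    """Convert a transcript-level profile M to RNAP flux J = gamma * M.

    Output stays on an arbitrary scale (units ``arb_flux``).
    """
    if profile.units != UNIT_ARB_MRNA:
        raise ValueError(f"expected units {UNIT_ARB_MRNA!r}, got {profile.units!r}")
    return profile.with_values(profile.values * gamma, UNIT_ARB_FLUX)


def flux_to_absolute(
    profile: StrandedProfile,
    consts: CalibrationConstants = CalibrationConstants(),
    total: bool = False,
) -> StrandedProfile:
    """Convert arbitrary flux (gamma*M) to absolute RNAP/s via the power law.

    Per-promoter flux is ``coeff * (gamma*M)**exp`` where the coefficient is
    the product of the copy ratio, the RPU conversion factor and the
    empirical power-law coefficient.  With ``total=True`` the result is
    additionally multiplied by the circuit plasmid copy number.
    """
    if profile.units != UNIT_ARB_FLUX:
        raise ValueError(f"expected units {UNIT_ARB_FLUX!r}, got {profile.units!r}")
    if (profile.values < 0).any():
        raise ValueError("negative flux input")
    values = consts.absolute_flux_coeff * profile.values**consts.powerlaw_exp
    units = UNIT_RNAP_PER_S_PER_PROMOTER
    if total:
        values = values * consts.n_circuit_copies
        units = UNIT_RNAP_PER_S_TOTAL
    return profile.with_values(values, units)


def map_psites_center_weighted(
    footprints: Sequence[AlignedFragment],
    reference_length: int,
    reference_id: str | None = None,
    length_range: tuple[int, int] = (23, 42),
    trim: int = 11,
) -> tuple[StrandedProfile, StrandedProfile]:
    """Map ribosome footprints to per-nucleotide occupancy, center-weighted.

    Footprints with length outside ``length_range`` are ignored.  Each
    retained footprint has ``trim`` nucleotides removed from either end and
    contributes ``1 / (length - 2*trim)`` to every nucleotide of the
    remaining center region, so the global sum of scores equals the number
    of retained footprints.
    """
    if reference_id is None:
        reference_id = footprints[0].reference_id if footprints else "ref"
    lo, hi = length_range
    sense_acc = np.zeros(reference_length + 1, dtype=float)
    anti_acc = np.zeros(reference_length + 1, dtype=float)
    if footprints:
        starts, ends, sense = _fragment_arrays(footprints)
        lengths = ends - starts
        keep = (lengths >= lo) & (lengths <= hi)
        starts, ends, sense, lengths = (
            starts[keep],
            ends[keep],
            sense[keep],
            lengths[keep],
        )
        weights = 1.0 / (lengths - 2 * trim)
        cstarts = starts + trim
        cends = ends - trim
        for acc, mask in ((sense_acc, sense), (anti_acc, ~sense)):
            np.add.at(acc, cstarts[mask], weights[mask])
            np.add.at(acc, cends[mask], -weights[mask])
    # cumulative sums of +w/-w pairs can leave O(eps) negative residue
    sense_prof = StrandedProfile(
        reference_id, SENSE, np.clip(np.cumsum(sense_acc[:-1]), 0.0, None), UNIT_ARB_MRNA
    )
    anti_prof = StrandedProfile(
        reference_id, ANTISENSE, np.clip(np.cumsum(anti_acc[:-1]), 0.0, None), UNIT_ARB_MRNA
    )
    return sense_prof, anti_prof


def normalize_occupancy_absolute(
    occupancies: Sequence[StrandedProfile],
    consts: CalibrationConstants = CalibrationConstants(),
) -> list[StrandedProfile]:
    """Scale a set of occupancy profiles so their global sum equals the
    total number of active ribosomes.  Units become ``ribosomes``."""
    total = sum(float(p.values.sum()) for p in occupancies)
    if total <= 0:
        raise ValueError("all-zero occupancy; cannot normalize")
    scale = consts.total_active_ribosomes / total
    return [p.with_values(p.values * scale, UNIT_RIBOSOMES) for p in occupancies]


def occupancy_per_transcript(
    occupancy: StrandedProfile,
    flux: StrandedProfile,
    gamma: float,
) -> StrandedProfile:
    """Ribosomes per mRNA: occupancy divided by transcript count J/gamma.

    Positions with zero flux get NaN (undefined) markers.
    """
    if occupancy.reference_id != flux.reference_id or occupancy.strand != flux.strand:
        raise ValueError("occupancy and flux profiles must share reference and strand")
    if occupancy.units != UNIT_RIBOSOMES:
        raise ValueError("occupancy must be in absolute ribosome units")
    if flux.units not in (UNIT_RNAP_PER_S_PER_PROMOTER, UNIT_RNAP_PER_S_TOTAL):
        raise ValueError("flux must be in absolute RNAP/s units")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = occupancy.values * gamma / flux.values
    values = np.where(flux.values > 0, values, np.nan)
    return occupancy.with_values(values, UNIT_RIBOSOMES_PER_MRNA)
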