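"""Gene-level expression quantities.

Ribosome density (with its trimming, start-elevation decay correction and
winsorization), steady-state mRNA counts, translation efficiency, ribosome
usage, proteome fractions, and the repressor off-target screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .profiles import (
    SENSE,
    UNIT_RIBOSOMES,
    UNIT_RNAP_PER_S_PER_PROMOTER,
    UNIT_RNAP_PER_S_TOTAL,
    StrandedProfile,
)

__all__ = [
    "GeneInterval",
    "GeneRecord",
    "TranslationConstants",
    "DecayModel",
    "fit_decay_model",
    "compute_rd",
    "steady_state_mrna",
    "translation_efficiency",
    "ribosome_usage",
    "proteome_fraction",
    "offtarget_screen",
]

EDGE_TRIM_NT = 15  # first and last five codons


class GeneInterval(NamedTuple):
    reference_id: str
    start: int
    end: int
    strand: str


@dataclass
class GeneRecord:
    """Per-gene quantities; NaN marks not-yet-computed fields."""

    name: str
    gene: GeneInterval
    molecular_weight: float = float("nan")
    fpkm: float = float("nan")
    rd: float = float("nan")
    m_ss: float = float("nan")
    te: float = float("nan")
    ribosome_usage: float = float("nan")
    proteome_fraction: float = float("nan")


@dataclass(frozen=True)
class TranslationConstants:
    omega: float = 15.0  # ribosome elongation rate, s^-1
    gamma: float = 0.0067

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.gamma <= 0:
            raise ValueError("translation constants must be positive")


@dataclass(frozen=True)
class DecayModel:
    """Start-proximal occupancy elevation, f(d) = 1 + a * exp(-d / lam).

    Normalized so f(d) -> 1 far from the start codon; dividing occupancy
    by f(d) removes the initiation-proximal elevation.
    """

    a: float = 0.0
    lam: float = 1.0

    def __call__(self, d: np.ndarray | float) -> np.ndarray | float:
        if self.a == 0.0:
            return np.ones_like(np.asarray(d, dtype=float))
        return 1.0 + self.a * np.exp(-np.asarray(d, dtype=float) / self.lam)

    @classmethod
    def identity(cls) -> "DecayModel":
        return cls(a=0.0, lam=1.0)


def _gene_values(profile: StrandedProfile, gene: GeneInterval) -> np.ndarray:
    """Occupancy over a gene ordered 5'->3' in the direction of translation."""
    vals = profile.values[gene.start : gene.end]
    return vals if gene.strand == SENSE else vals[::-1]


def fit_decay_model(
    occupancies: Sequence[StrandedProfile],
    genes: Sequence[GeneInterval],
    fit_range_nt: int = 300,
    min_genes: int = 20,
) -> DecayModel:
    """Fit the metagene start-proximal decay from a set of genes.

    Builds a metagene profile of occupancy versus distance from the start
    codon (each gene normalized by its own mean so genes weigh equally)
    and fits c + A*exp(-d/lam) over the first ``fit_range_nt`` nt; the
    correction is the rescaled f(d) = 1 + (A/c)*exp(-d/lam).  A degenerate
    fit (a <= 0) falls back to the identity model with a warning.
    """
    by_key = {(p.reference_id, p.strand): p for p in occupancies}
    rows = []
    for gene in genes:
        profile = by_key.get((gene.reference_id, gene.strand))
        if profile is None:
            continue
        vals = _gene_values(profile, gene)[:fit_range_nt]
        mean = vals.mean() if len(vals) else 0.0
        if mean <= 0:
            continue
        padded = np.full(fit_range_nt, np.nan)
        padded[: len(vals)] = vals / mean
        rows.append(padded)
    if len(rows) < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with nonzero occupancy, got {len(rows)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        metagene = np.nanmean(np.vstack(rows), axis=0)
    d = np.arange(fit_range_nt, dtype=float)
    ok = np.isfinite(metagene)
    try:
        (c, amp, lam), _ = curve_fit(
            lambda x, c, amp, lam: c + amp * np.exp(-x / lam),
            d[ok],
            metagene[ok],
            p0=(float(np.median(metagene[ok][-50:])), float(metagene[ok][0] - 1.0), 50.0),
            bounds=([1e-12, -np.inf, 1.0], [np.inf, np.inf, float(fit_range_nt)]),
            maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("decay-model fit failed to converge; using identity model")
        return DecayModel.identity()
    a = amp / c
    if a <= 0:
        warnings.warn("degenerate decay-model fit (a <= 0); using identity model")
        return DecayModel.identity()
    return DecayModel(a=float(a), lam=float(lam))


def compute_rd(
    occupancy: StrandedProfile,
    gene: GeneInterval,
    decay_model: DecayModel | None = None,
    winsorize: bool = True,
    winsorize_density_threshold: float = 1.0,
) -> float:
    """Ribosome density: trimmed, decay-corrected mean occupancy of a gene.

    The first and last five codons (15 nt each end) are excluded.  Each
    position is divided by the decay correction at its distance from the
    start codon.  When the mean raw density over the trimmed gene exceeds
    the threshold, values are 90%-winsorized (clipped at the 5th and 95th
    percentile) before averaging.
    """
    if gene.end - gene.start <= 2 * EDGE_TRIM_NT:
        raise ValueError("gene too short to trim five codons from each end")
    vals = _gene_values(occupancy, gene)[EDGE_TRIM_NT:-EDGE_TRIM_NT]
    d = np.arange(EDGE_TRIM_NT, EDGE_TRIM_NT + len(vals), dtype=float)
    model = decay_model or DecayModel.identity()
    corrected = vals / np.asarray(model(d), dtype=float)
    if winsorize and vals.mean() > winsorize_density_threshold:
        lo, hi = np.percentile(corrected, [5.0, 95.0])
        corrected = np.clip(corrected, lo, hi)
    return float(corrected.mean())


def steady_state_mrna(
    flux: StrandedProfile,
    gene: GeneInterval,
    gamma: float,
    window_shift: int = 0,
    window_nt: int = 10,
) -> float:
    """Steady-state transcript count from the flux at the end of a gene.

    Averages the flux over a 10 nt window at the 3' end of the gene
    (optionally shifted upstream into the coding region to dodge internal
    promoters) and divides by the mRNA degradation rate.
    """
    if flux.units not in (UNIT_RNAP_PER_S_PER_PROMOTER, UNIT_RNAP_PER_S_TOTAL):
        raise ValueError("flux must be in absolute RNAP/s units")
    if gene.strand == SENSE:
        win_end = gene.end - window_shift
        win_start = win_end - window_nt
    else:
        win_start = gene.start + window_shift
        win_end = win_start + window_nt
    if win_start < gene.start or win_end > gene.end:
        raise ValueError("averaging window falls outside the gene")
    return flux.interval_mean(win_start, win_end) / gamma


def translation_efficiency(
    rd: float,
    m_ss: float,
    consts: TranslationConstants = TranslationConstants(),
) -> float:
    """TE = RD * omega / m_ss, in proteins per mRNA per second.

    Returns NaN when the steady-state transcript count is zero.
    """
    if m_ss == 0:
        return float("nan")
    return rd * consts.omega / m_ss


def ribosome_usage(occupancy: StrandedProfile, gene: GeneInterval) -> float:
    """Total ribosomes sequestered by a gene: occupancy summed over it."""
    if occupancy.units != UNIT_RIBOSOMES:
        raise ValueError("occupancy must be in absolute ribosome units")
    return float(occupancy.values[gene.start : gene.end].sum())


def proteome_fraction(rd: np.ndarray, molecular_weight: np.ndarray) -> np.ndarray:
    """Proteome fraction per gene: RD_i*MW_i / sum_k RD_k*MW_k."""
    rd = np.asarray(rd, dtype=float)
    mw = np.asarray(molecular_weight, dtype=float)
    if (rd < 0).any() or (mw < 0).any():
        raise ValueError("RD and MW must be nonnegative")
    product = rd * mw
    total = product.sum()
    if total <= 0:
        raise ValueError("all-zero RD*MW; proteome fractions undefined")
    return product / total


def offtarget_screen(
    rd_by_state: pd.DataFrame,
    repressor_on_states: Sequence[str],
    fold_threshold: float = 5.0,
) -> pd.DataFrame:
    """Screen native genes for putative repressor off-target binding.

    ``rd_by_state`` holds one row per gene and one column per circuit
    state.  Fold-repression is mean RD over repressor-OFF states divided
    by mean RD over repressor-ON states; genes strictly above the
    threshold are returned sorted by descending fold.  A zero ON-state
    mean yields an infinite fold marker.
    """
    on = [s for s in rd_by_state.columns if s in set(repressor_on_states)]
    off = [s for s in rd_by_state.columns if s not in set(repressor_on_states)]
    if not on or not off:
        raise ValueError("both ON and OFF state subgroups must be non-empty")
    rd_on = rd_by_state[on].mean(axis=1)
    rd_off = rd_by_state[off].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = rd_off / rd_on
    fold = fold.where(~((rd_on == 0) & (rd_off > 0)), np.inf)
    fold = fold.where(~((rd_on == 0) & (rd_off == 0)), np.nan)
    result = pd.DataFrame({"fold_repression": fold})
    flagged = result[result["fold_repression"] > fold_threshold]
    return flagged.sort_values("fold_repression", ascending=False)
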