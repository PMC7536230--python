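"""TSS/TTS detection and promoter / terminator / ribozyme quantification.

All callers operate on flux profiles (any consistent unit scale).  A small
pseudo-flux is added to ratio denominators so zero-coverage stretches do
not produce infinities; calls whose denominator was dominated by the
pseudo-flux are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .profiles import ANTISENSE, SENSE, AlignedFragment, StrandedProfile

__all__ = [
    "WindowConfig",
    "SiteCall",
    "CERresult",
    "call_tss",
    "call_tts",
    "promoter_strength",
    "terminator_strength",
    "ribozyme_ce",
]

TSS = "TSS"
TTS = "TTS"


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry and thresholds shared by the site callers.

    ``n`` is the averaging-window length, ``A`` the gap between a site and
    its windows, ``ratio_threshold`` the step / averaged-window ratio above
    which a site is called.  ``pseudo_flux_scale`` times the profile
    maximum is added to ratio denominators.
    """

    n: int = 10
    A: int = 10
    ratio_threshold: float = 5.0
    pseudo_flux_scale: float = 1e-12

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must be > 1")


@dataclass(frozen=True)
class SiteCall:
    position: int
    strand: str
    kind: str
    score: float
    ribozyme_coincident: bool = False
    pseudo_denominator: bool = False


class CERresult(NamedTuple):
    """Ribozyme cleavage-efficiency estimate with its fragment counts."""

    ce: float
    f_cut: int
    f_uncut: int


def _merge_adjacent(
    positions: np.ndarray, scores: np.ndarray, pseudo: np.ndarray, max_gap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of calls closer than ``max_gap`` nt to the max-score one.

    Calls whose ratio denominator was pseudo-flux-dominated lose to calls
    with real coverage in the denominator, whatever their ratio: a zero
    denominator inflates the ratio arbitrarily.
    """
    if len(positions) == 0:
        return positions, scores
    order = np.argsort(positions)
    positions, scores, pseudo = positions[order], scores[order], pseudo[order]
    merged_pos, merged_score = [], []
    run_start = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or positions[i] - positions[i - 1] > max_gap:
            run = slice(run_start, i)
            run_scores = np.where(pseudo[run], -1.0, scores[run])
            if run_scores.max() < 0:  # all pseudo: fall back to raw scores
                run_scores = scores[run]
            best = run_start + int(np.argmax(run_scores))
            merged_pos.append(positions[best])
            merged_score.append(scores[best])
            run_start = i
    return np.asarray(merged_pos), np.asarray(merged_score)


def call_tss(
    flux: StrandedProfile,
    cfg: WindowConfig = WindowConfig(),
    ribozyme_sites: Sequence[int] = (),
) -> list[SiteCall]:
    """Call transcription start sites from neighboring-position flux ratios.

    Sense strand: a TSS is called at x+1 wherever J(x+1)/J(x) exceeds the
    threshold; the antisense caller uses the inverse ratio and calls at x.
    Super-threshold steps within ``n`` nt of each other are merged to the
    largest single-step ratio.  Calls at a supplied ribozyme cleavage site
    are flagged ``ribozyme_coincident``.
    """
    v = flux.values
    if len(v) < 2 or v.max() <= 0:
        return []
    eps = cfg.pseudo_flux_scale * v.max()
    if flux.strand == SENSE:
        denom = v[:-1]
        ratios = v[1:] / (denom + eps)
        call_positions = np.arange(1, len(v))
    else:
        denom = v[1:]
        ratios = v[:-1] / (denom + eps)
        call_positions = np.arange(0, len(v) - 1)
    hits = ratios > cfg.ratio_threshold
    positions, scores = _merge_adjacent(
        call_positions[hits], ratios[hits], denom[hits] <= eps, max_gap=cfg.n
    )
    denom_by_pos = dict(zip(call_positions[hits].tolist(), denom[hits].tolist()))
    sites = set(int(s) for s in ribozyme_sites)
    return [
        SiteCall(
            position=int(p),
            strand=flux.strand,
            kind=TSS,
            score=float(s),
            ribozyme_coincident=int(p) in sites,
            pseudo_denominator=denom_by_pos.get(int(p), eps) <= eps,
        )
        for p, s in zip(positions, scores)
    ]


def _window_means(v: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upstream/downstream window means around each interior position x.

    up(x) = mean(v[x-n:x]), dn(x) = mean(v[x:x+n]) for x in [n, len(v)-n].
    """
    csum = np.concatenate(([0.0], np.cumsum(v)))
    x = np.arange(n, len(v) - n + 1)
    up = (csum[x] - csum[x - n]) / n
    dn = (csum[x + n] - csum[x]) / n
    return x, up, dn


def call_tts(flux: StrandedProfile, cfg: WindowConfig = WindowConfig()) -> list[SiteCall]:
    """Call transcription termination sites via the averaged-window ratio.

    AWR(x) compares the mean flux over the n nt upstream of x to the n nt
    downstream (inverted on the antisense strand).  Contiguous runs above
    the threshold are collapsed to the maximum-AWR position; ties pick the
    most upstream position in the direction of transcription.
    """
    v = flux.values
    if len(v) <= 2 * cfg.n:
        raise ValueError("profile too short for the averaging windows")
    if v.max() <= 0:
        return []
    eps = cfg.pseudo_flux_scale * v.max()
    x, up, dn = _window_means(v, cfg.n)
    if flux.strand == SENSE:
        awr = up / (dn + eps)
        denom = dn
    else:
        awr = dn / (up + eps)
        denom = up
    hits = awr > cfg.ratio_threshold
    calls: list[SiteCall] = []
    i = 0
    while i < len(x):
        if not hits[i]:
            i += 1
            continue
        j = i
        while j < len(x) and hits[j]:
            j += 1
        run = slice(i, j)
        run_awr = awr[run]
        if flux.strand == SENSE:
            best = i + int(np.argmax(run_awr))  # first occurrence = 5'-most
        else:
            best = i + len(run_awr) - 1 - int(np.argmax(run_awr[::-1]))
        calls.append(
            SiteCall(
                position=int(x[best]),
                strand=flux.strand,
                kind=TTS,
                score=float(awr[best]),
                pseudo_denominator=denom[best] <= eps,
            )
        )
        i = j
    return calls


def _site_windows(
    flux: StrandedProfile, position: int, cfg: WindowConfig
) -> tuple[float, float] | None:
    """Means of the upstream and downstream windows of Eq.-style geometry.

    Returns None (no-estimate) when either window would leave the profile.
    """
    lo = position - cfg.A - cfg.n
    hi = position + cfg.A + cfg.n
    if lo < 0 or hi > len(flux.values):
        return None
    upstream = float(flux.values[lo : position - cfg.A].mean())
    downstream = float(flux.values[position + cfg.A : hi].mean())
    return upstream, downstream


def promoter_strength(
    flux: StrandedProfile,
    tss: SiteCall | int,
    cfg: WindowConfig = WindowConfig(),
) -> float | None:
    """Promoter activity as the window-mean flux difference across a TSS.

    deltaJ = mean(J[TSS+A : TSS+A+n]) - mean(J[TSS-A-n : TSS-A]); the
    result is multiplied by -1 on the antisense strand.  Returns None when
    a window would extend past the profile.
    """
    position = tss.position if isinstance(tss, SiteCall) else int(tss)
    windows = _site_windows(flux, position, cfg)
    if windows is None:
        return None
    upstream, downstream = windows
    delta = downstream - upstream
    if flux.strand == ANTISENSE:
        delta = -delta
    return delta


def terminator_strength(
    flux: StrandedProfile,
    tts: SiteCall | int,
    cfg: WindowConfig = WindowConfig(),
) -> float | None:
    """Terminator strength as the fold-decrease in flux across a TTS.

    T_S = upstream window mean / downstream window mean (inverted on the
    antisense strand).  Returns None when a window is out of bounds.
    """
    position = tts.position if isinstance(tts, SiteCall) else int(tts)
    windows = _site_windows(flux, position, cfg)
    if windows is None:
        return None
    upstream, downstream = windows
    eps = cfg.pseudo_flux_scale * max(flux.values.max(), 1.0)
    if flux.strand == SENSE:
        return upstream / (downstream + eps)
    return downstream / (upstream + eps)


def ribozyme_ce(
    fragments: Sequence[AlignedFragment],
    cleavage_site: int,
    strand: str,
) -> CERresult:
    """Ribozyme cleavage efficiency from raw fragments around the site.

    Cut fragments either end exactly at the cleavage site or begin with
    it; uncut fragments overlap the site.  CE = F_cut / (F_cut + F_uncut);
    the CE is NaN when no informative fragments exist.
    """
    from .profiles import SENSE as _SENSE
    from .profiles import FragmentArray

    if isinstance(fragments, FragmentArray):
        on_strand = fragments.sense == (strand == _SENSE)
        starts = fragments.starts[on_strand]
        ends = fragments.ends[on_strand]
        cut = (ends == cleavage_site) | (starts == cleavage_site)
        uncut = ~cut & (starts < cleavage_site) & (ends > cleavage_site)
        f_cut = int(cut.sum())
        f_uncut = int(uncut.sum())
    else:
        f_cut = 0
        f_uncut = 0
        for frag in fragments:
            if frag.strand != strand:
                continue
            if frag.end == cleavage_site or frag.start == cleavage_site:
                f_cut += 1
            elif frag.start < cleavage_site < frag.end:
                f_uncut += 1
    total = f_cut + f_uncut
    ce = f_cut / total if total else float("nan")
    return CERresult(ce, f_cut, f_uncut)
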