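"""IP-vs-input enrichment peak calling with a sliding-window Poisson test.

The caller follows the MACS-style model-free ("nomodel") scheme: slide
fixed windows along the genome, count IP fragment starts per window,
and test each count against a Poisson expectation derived from the
depth-scaled input. The background rate for a window is the maximum of
the genome-wide input rate and local input rates measured over
surrounding windows (1 kb and 10 kb by default), floored at the
genome-wide IP expectation ``ip_total * window / effective_genome_size``
— a local-lambda surrogate that guards against calling peaks in locally
noisy background. Significant windows are merged, short merged
intervals are dropped (the default 23 nt minimum matches the fragment
resolution of photo-crosslinking-assisted m6A-seq), and each peak's
summit is the leftmost position of maximal IP depth.

No multiple-testing correction is applied to window p-values; peaks are
reported at a raw Poisson tail cutoff (default 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .gene_context import GeneModel
from .synthetic_data import ReadSet

__all__ = [
    "CoverageTrack",
    "PeakCallerConfig",
    "Peak",
    "build_coverage",
    "scale_factor",
    "poisson_tail",
    "call_peaks",
]


@dataclass
class CoverageTrack:
    """Per-position fragment depth over the genome for one sample."""

    depth: np.ndarray
    total_fragments: int
    sample_tag: str

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.depth) and self.depth.min() < 0:
            raise ValueError("coverage depth must be non-negative")


@dataclass
class PeakCallerConfig:
    """Tunable parameters of the sliding-window caller."""

    p_threshold: float = 1e-5
    effective_genome_size: int = 6_000_000
    window: int = 50
    step: int = 25
    merge_gap: int = 30
    min_length: int = 23
    local_windows: tuple[int, ...] = (1000, 10000)

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_length < 1 or self.window < 1 or self.step < 1:
            raise ValueError("window, step and min_length must be positive")


@dataclass
class Peak:
    """A called enrichment interval (0-based, half-open)."""

    start: int
    end: int
    summit: int
    p_value: float
    fold_enrichment: float
    gene_id: str | None = None
    context: object = None

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie within the peak")

    def __len__(self) -> int:
        return self.end - self.start


def build_coverage(reads: ReadSet, genome_length: int | None = None) -> CoverageTrack:
    """Per-position depth of a read set via a difference array.

    Total depth over positions equals the summed fragment lengths
    (coverage conservation).
    """
    L = reads.genome_length if genome_length is None else genome_length
    if len(reads.starts) and (
        reads.starts.min() < 0 or (reads.starts + reads.lengths).max() > L
    ):
        raise ValueError("read outside genome bounds")
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, reads.starts, 1)
    np.add.at(diff, reads.starts + reads.lengths, -1)
    return CoverageTrack(
        depth=np.cumsum(diff[:-1]),
        total_fragments=len(reads),
        sample_tag=reads.sample_tag,
    )


def scale_factor(ip_total: int, input_total: int) -> float:
    """Depth normalization: multiply input-derived rates by ip/input."""
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("fragment totals must be positive")
    return ip_total / input_total


def poisson_tail(k: int, lam: float) -> float:
    """Upper-tail P(X >= k) for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def _window_counts(starts: np.ndarray, L: int, win_starts: np.ndarray, width: int) -> np.ndarray:
    """Fragment-start counts in windows [w, w+width), centered clipping at bounds."""
    order = np.sort(starts)
    lo = np.searchsorted(order, win_starts)
    hi = np.searchsorted(order, win_starts + width)
    return (hi - lo).astype(np.int64)


def call_peaks(
    ip_reads: ReadSet,
    input_reads: ReadSet,
    genes: Sequence[GeneModel] | None = None,
    config: PeakCallerConfig | None = None,
) -> list[Peak]:
    """Call IP-over-input enrichment peaks.

    Slides ``config.window``-nt windows at ``config.step`` spacing; each
    window's IP fragment-start count is tested against a Poisson rate
    built from the depth-scaled input (max of global and local rates,
    floored at the genome-wide IP expectation). Windows at
    ``p <= p_threshold`` are merged when separated by at most
    ``merge_gap`` nt, merged intervals shorter than ``min_length`` are
    dropped, and the summit is the leftmost maximal-IP-depth position.
    """
    if config is None:
        config = PeakCallerConfig()
    if ip_reads.genome_length != input_reads.genome_length:
        raise ValueError("IP and input must share the genome length")
    L = ip_reads.genome_length
    ip_total, input_total = len(ip_reads), len(input_reads)
    if ip_total == 0:
        return []
    if input_total == 0:
        raise ValueError("input read set is empty")

    w, step = config.window, config.step
    win_starts = np.arange(0, max(L - w, 0) + 1, step)
    k = _window_counts(ip_reads.starts, L, win_starts, w)

    sf = scale_factor(ip_total, input_total)
    centers = win_starts + w // 2
    # background rate per nt: scaled input — global, window-scale and local.
    # The window-scale term keeps genic windows from being tested against
    # rates diluted by intergenic gaps inside the wider local spans.
    rate = np.full(len(win_starts), input_total / L, dtype=float)
    rate = np.maximum(rate, _window_counts(input_reads.starts, L, win_starts, w) / w)
    for span in config.local_windows:
        lo = np.clip(centers - span // 2, 0, L)
        local = _window_counts(input_reads.starts, L, lo, span)
        width = np.minimum(lo + span, L) - lo
        rate = np.maximum(rate, local / np.maximum(width, 1))
    lam = np.maximum(rate * sf * w, ip_total * w / config.effective_genome_size)

    pvals = stats.poisson.sf(k - 1, lam)
    pvals = np.where(k == 0, 1.0, pvals)
    sig = pvals <= config.p_threshold
    if not sig.any():
        return []

    ip_cov = build_coverage(ip_reads).depth
    input_cov = build_coverage(input_reads).depth

    peaks: list[Peak] = []
    idx = np.flatnonzero(sig)
    cur_start = int(win_starts[idx[0]])
    cur_end = cur_start + w
    cur_p = float(pvals[idx[0]])
    for j in idx[1:]:
        ws = int(win_starts[j])
        if ws - cur_end <= config.merge_gap:
            cur_end = max(cur_end, ws + w)
            cur_p = min(cur_p, float(pvals[j]))
        else:
            _append_peak(peaks, cur_start, cur_end, cur_p, ip_cov, input_cov, sf, config, L)
            cur_start, cur_end, cur_p = ws, ws + w, float(pvals[j])
    _append_peak(peaks, cur_start, cur_end, cur_p, ip_cov, input_cov, sf, config, L)
    return peaks


def _append_peak(
    peaks: list[Peak],
    start: int,
    end: int,
    p: float,
    ip_cov: np.ndarray,
    input_cov: np.ndarray,
    sf: float,
    config: PeakCallerConfig,
    L: int,
) -> None:
    end = min(end, L)
    if end - start < config.min_length:
        return
    seg = ip_cov[start:end]
    summit = start + int(np.argmax(seg))  # argmax is leftmost on ties
    span = config.local_windows[0] if config.local_windows else 1000
    lo, hi = max(0, summit - span // 2), min(L, summit + span // 2)
    bg = max(float(input_cov[lo:hi].mean()) * sf, float(ip_cov.mean()), 1e-12)
    peaks.append(
        Peak(
            start=start,
            end=end,
            summit=summit,
            p_value=p,
            fold_enrichment=float(ip_cov[summit]) / bg,
        )
    )
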