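"""Mixing and work analysis: radial distribution functions, the max[g(r)]
relaxation metric, exponential relaxation fits, speedup ratios, and work
statistics.

The mixing observable is the radial distribution function g(r) of the head
beads of one species.  In a demixed configuration same-species heads are
clustered and the tallest g(r) peak is high; as the mixture equilibrates the
peak decays to the plateau of the uniformly mixed state.  Fitting
``y(t) = y_inf + a exp(-k t)`` with t = cumulative force evaluations gives a
relaxation rate per force evaluation; ratios of rates between samplers are
the speedup figures of merit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import Frame

__all__ = [
    "RdfResult",
    "MixingSeries",
    "RelaxationFit",
    "FitError",
    "radial_distribution",
    "max_gr_series",
    "fit_exponential",
    "speedup",
    "acceptance_from_work",
    "WorkSummary",
    "work_summary",
]


class FitError(RuntimeError):
    """Relaxation fit failed to converge or the series does not decay."""


@dataclass
class RdfResult:
    bin_centers: np.ndarray
    g_values: np.ndarray
    bin_width: float
    selection: str
    n_frames: int

    def peak(self, r_min: float = 0.0) -> float:
        """Highest g value among bins with center > r_min."""
        mask = self.bin_centers > r_min
        if not np.any(mask):
            raise ValueError("no bins beyond r_min")
        return float(self.g_values[mask].max())


@dataclass
class MixingSeries:
    """max[g(r)] against cumulative force evaluations."""

    force_evals: np.ndarray
    max_gr: np.ndarray

    def __post_init__(self) -> None:
        self.force_evals = np.asarray(self.force_evals, dtype=np.float64)
        self.max_gr = np.asarray(self.max_gr, dtype=np.float64)
        if self.force_evals.size != self.max_gr.size:
            raise ValueError("series lengths differ")
        if self.force_evals.size > 1 and np.any(np.diff(self.force_evals) <= 0):
            raise ValueError("force_evals must be strictly increasing")


@dataclass
class RelaxationFit:
    """Parameters of y = y_inf + a exp(-k t) with 1-sigma uncertainties."""

    plateau: float
    amplitude: float
    rate: float
    plateau_stderr: float
    amplitude_stderr: float
    rate_stderr: float
    residual_norm: float


def _selection_mask(frame: Frame, selection: str) -> np.ndarray:
    return frame.labels == selection


def _pair_distances(pos: np.ndarray, frame: Frame) -> np.ndarray:
    """All unordered pair distances with the minimum-image convention."""
    n = pos.shape[0]
    if n < 2:
        return np.empty(0)
    iu = np.triu_indices(n, k=1)
    dr = pos[iu[0]] - pos[iu[1]]
    for k in range(frame.dim):
        if frame.periodic[k]:
            L = frame.box_lengths[k]
            dr[:, k] -= L * np.round(dr[:, k] / L)
    return np.sqrt(np.sum(dr * dr, axis=1))


def radial_distribution(
    frames: list[Frame],
    selection: str = "HB",
    r_max: float | None = None,
    bin_width: float = 0.05,
    n_bins: int | None = None,
) -> RdfResult:
    """Same-selection g(r), frame-averaged, normalized for 2D (annulus) or
    3D (shell) geometry so an ideal gas gives g = 1."""
    if not frames:
        raise ValueError("need at least one frame")
    dim = frames[0].dim
    half_min_edge = 0.5 * float(min(fr.box_lengths.min() for fr in frames))
    if r_max is None:
        r_max = half_min_edge
    if r_max > half_min_edge + 1e-12:
        raise ValueError(
            f"r_max {r_max:.3f} exceeds half the smallest box edge {half_min_edge:.3f}"
        )
    if n_bins is None:
        n_bins = max(1, int(round(r_max / bin_width)))
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    ideal = np.zeros(n_bins)
    for fr in frames:
        mask = _selection_mask(fr, selection)
        n_sel = int(mask.sum())
        if n_sel == 0:
            raise ValueError(f"selection {selection!r} matches no particles")
        d = _pair_distances(fr.positions[mask], fr)
        counts += np.histogram(d, bins=edges)[0]
        n_pairs = n_sel * (n_sel - 1) / 2.0
        volume = float(np.prod(fr.box_lengths))
        if dim == 2:
            bin_measure = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        else:
            bin_measure = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        ideal += n_pairs * bin_measure / volume
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RdfResult(centers, g, float(edges[1] - edges[0]), selection, len(frames))


def max_gr_series(
    frames: list[Frame],
    selection: str = "HB",
    r_min_exclusion: float = 0.5,
    frames_per_point: int = 10,
    **rdf_kwargs,
) -> MixingSeries:
    """Blocked max[g(r)] against the force-evaluation stamp of each block.

    Frames are grouped into consecutive blocks of ``frames_per_point``;
    one g(r) is computed per block (variance reduction) and its highest
    peak beyond the excluded-volume region ``r > r_min_exclusion`` recorded
    at the block's last force-evaluation stamp.
    """
    if not frames:
        raise ValueError("need at least one frame")
    xs, ys = [], []
    for start in range(0, len(frames), frames_per_point):
        block = frames[start : start + frames_per_point]
        if len(block) < frames_per_point and start > 0:
            break  # drop ragged tail, keep blocks comparable
        rdf = radial_distribution(block, selection=selection, **rdf_kwargs)
        xs.append(block[-1].force_evals)
        ys.append(rdf.peak(r_min_exclusion))
    return MixingSeries(np.asarray(xs, dtype=np.float64), np.asarray(ys))


def fit_exponential(
    series: MixingSeries,
    fix_plateau: float | None = None,
) -> RelaxationFit:
    """Nonlinear least-squares fit of y = y_inf + a exp(-k t).

    Initialization: y_inf from the series tail (or ``fix_plateau``), then a
    log-linear regression of (y - y_inf) for the rate.  A series that does
    not decay raises :class:`FitError` rather than returning a bogus fit.
    """
    t = series.force_evals
    y = series.max_gr
    if t.size < 5:
        raise FitError(f"need >= 5 points to fit, got {t.size}")
    if np.ptp(y) <= 0:
        raise FitError("constant series: nothing to fit")

    # scale t to O(1) for conditioning; rates are converted back at the end
    t_scale = float(t.max() - t.min()) or 1.0
    ts = (t - t.min()) / t_scale

    tail = max(3, y.size // 5)
    y_inf0 = float(fix_plateau) if fix_plateau is not None else float(np.mean(y[-tail:]))
    resid0 = y - y_inf0
    a0 = float(y[0] - y_inf0) if abs(y[0] - y_inf0) > 1e-12 else float(np.ptp(y))

    # candidate rate initializations: log-linear regression of the positive
    # residuals plus a 1/e first-crossing heuristic (robust for fast decays)
    k0s = [1.0]
    pos = resid0 > max(1e-12, 1e-6 * np.ptp(y))
    if pos.sum() >= 2:
        slope = np.polyfit(ts[pos], np.log(resid0[pos]), 1)[0]
        if slope < 0:
            k0s.append(-slope)
    if a0 > 0:
        below = np.nonzero(resid0 <= 0.3679 * a0)[0]
        if below.size and ts[below[0]] > 0:
            k0s.append(1.0 / ts[below[0]])

    best = None
    last_exc: Exception | None = None
    for k0 in k0s:
        try:
            if fix_plateau is None:
                popt, pcov = curve_fit(
                    lambda tt, y_inf, a, k: y_inf + a * np.exp(-k * tt),
                    ts, y, p0=[y_inf0, max(a0, 1e-12), k0],
                    bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
                y_inf_f, a_f, k_f = popt
                e_yinf_f, e_a_f, e_k_f = np.sqrt(np.diag(pcov))
            else:
                popt, pcov = curve_fit(
                    lambda tt, a, k: y_inf0 + a * np.exp(-k * tt),
                    ts, y, p0=[max(a0, 1e-12), k0],
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    maxfev=20000,
                )
                a_f, k_f = popt
                y_inf_f = y_inf0
                e_a_f, e_k_f = np.sqrt(np.diag(pcov))
                e_yinf_f = 0.0
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
            continue
        rnorm = float(np.linalg.norm(y - (y_inf_f + a_f * np.exp(-k_f * ts))))
        if best is None or rnorm < best[0]:
            best = (rnorm, y_inf_f, a_f, k_f, e_yinf_f, e_a_f, e_k_f)
    if best is None:
        raise FitError(f"exponential fit did not converge: {last_exc}")
    _, y_inf, a, k, e_yinf, e_a, e_k = best
    if not np.isfinite(k) or k <= 0 or a <= 1e-10 * max(abs(y_inf0), np.ptp(y)):
        raise FitError(
            f"series does not decay (fitted amplitude {a:.3g}, rate {k:.3g})"
        )
    resid = y - (y_inf + a * np.exp(-k * ts))
    # the internal amplitude is referenced to the first sample; report it at
    # t = 0 in original time units
    t0_factor = math.exp(min(k * float(t.min()) / t_scale, 50.0))
    return RelaxationFit(
        plateau=float(y_inf),
        amplitude=float(a * t0_factor),
        rate=float(k / t_scale),
        plateau_stderr=float(e_yinf),
        amplitude_stderr=float(e_a * t0_factor),
        rate_stderr=float(e_k / t_scale),
        residual_norm=float(np.linalg.norm(resid)),
    )


def speedup(
    fit_enhanced: RelaxationFit, fit_reference: RelaxationFit
) -> tuple[float, float]:
    """Rate ratio k_enhanced / k_reference with first-order error propagation."""
    if fit_reference.rate <= 0:
        raise ValueError("reference rate must be positive")
    ratio = fit_enhanced.rate / fit_reference.rate
    rel = math.sqrt(
        (fit_enhanced.rate_stderr / fit_enhanced.rate) ** 2
        + (fit_reference.rate_stderr / fit_reference.rate) ** 2
    )
    return ratio, ratio * rel


def acceptance_from_work(
    work_samples,
    kT: float,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, float]:
    """Average acceptance probability E[min(1, exp(-w/kT))] estimated from
    exploratory work values, with a bootstrap standard error."""
    w = np.asarray(work_samples, dtype=np.float64)
    if w.size == 0:
        raise ValueError("need at least one work sample")
    p = np.minimum(1.0, np.exp(-w / kT))
    mean = float(p.mean())
    if w.size == 1 or n_boot <= 0:
        return mean, 0.0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, p.size, size=(n_boot, p.size))
    boots = p[idx].mean(axis=1)
    return mean, float(boots.std(ddof=1))


@dataclass
class WorkSummary:
    """Histogram plus per-term mean work and percentage decomposition."""

    hist_counts: np.ndarray
    hist_edges: np.ndarray
    mean_total: float
    mean_vdw: float
    mean_coulomb: float
    mean_bonded: float
    pct_vdw: float
    pct_coulomb: float
    pct_bonded: float
    n_attempts: int


def work_summary(work_log, bins: int = 30) -> WorkSummary:
    """Summarize a work log (DataFrame with w_total/w_vdw/w_coulomb/w_bonded
    columns, or any mapping of such arrays); percentages are per-term mean
    work as a fraction of the mean total over the same (matched) attempts."""
    total = np.asarray(work_log["w_total"], dtype=np.float64)
    vdw = np.asarray(work_log["w_vdw"], dtype=np.float64)
    coul = np.asarray(work_log["w_coulomb"], dtype=np.float64)
    bond = np.asarray(work_log["w_bonded"], dtype=np.float64)
    if total.size == 0:
        raise ValueError("empty work log")
    counts, edges = np.histogram(total, bins=bins)
    m_tot = float(total.mean())
    m_v, m_c, m_b = float(vdw.mean()), float(coul.mean()), float(bond.mean())
    if m_tot != 0:
        pcts = (100.0 * m_v / m_tot, 100.0 * m_c / m_tot, 100.0 * m_b / m_tot)
    else:
        pcts = (float("nan"),) * 3
    return WorkSummary(
        counts, edges, m_tot, m_v, m_c, m_b, *pcts, n_attempts=int(total.size)
    )
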