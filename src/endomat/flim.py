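"""Two-lifetime TCSPC unmixing.

Live-cell FLIM of EGFP-EEA1 collects too few photons per pixel for free
lifetime fitting, so decays are decomposed onto two *fixed* lifetime
components determined in fixed-cell experiments: a short, FRET-quenched
component reporting N-terminally bound EEA1 (the GFP sits close to
Rab5-RFP) and a long component reporting C-terminally bound EEA1 (GFP far
from the membrane).  Splitting each pixel's photons between the two
components yields an "NT-EEA1" and a "CT-EEA1" channel.

The instrument response is modelled as a Gaussian, so each component's
arrival-time density is an exponentially modified Gaussian
(``scipy.stats.exponnorm``); fits are Poisson maximum likelihood with the
lifetimes held fixed and only the two amplitudes and a flat background
free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import exponnorm

__all__ = [
    "DecayModel",
    "DecayFit",
    "TerminusImagePair",
    "InsufficientPhotonsError",
    "fit_decay",
    "unmix_frame",
    "nc_ratio_trace",
    "moving_average",
    "classify_pair",
]


class InsufficientPhotonsError(ValueError):
    """Raised when a histogram holds too few photons for a stable fit."""


@dataclass(frozen=True)
class DecayModel:
    """Fixed two-component decay model on a TCSPC window.

    Parameters
    ----------
    tau1, tau2 : float
        Component lifetimes in ns.  ``tau1`` is the short (FRET,
        N-terminal) component, ``tau2`` the long (C-terminal) one.
    irf_sigma : float
        Gaussian instrument-response width (ns).
    t0 : float
        IRF centre within the window (ns).
    window : float
        TCSPC window length (ns).
    n_bins : int
        Number of histogram bins over the window.
    """

    tau1: float = 1.006
    tau2: float = 2.600
    irf_sigma: float = 0.1
    t0: float = 2.0
    window: float = 12.5
    n_bins: int = 256

    def __post_init__(self) -> None:
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("need 0 < tau1 < tau2")
        if self.window <= 0 or self.n_bins < 2:
            raise ValueError("window must be > 0 and n_bins >= 2")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.window, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def component_bin_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin arrival probabilities for each component.

        Each component is Exp(tau) convolved with the Gaussian IRF, i.e. an
        exponentially modified Gaussian; probabilities are renormalised over
        the window (truncation losses are tiny for these lifetimes).
        """
        edges = self.bin_edges
        out = []
        for tau in (self.tau1, self.tau2):
            if self.irf_sigma > 0:
                dist = exponnorm(K=tau / self.irf_sigma, loc=self.t0,
                                 scale=self.irf_sigma)
                cdf = dist.cdf(edges)
            else:
                cdf = np.where(edges >= self.t0,
                               1.0 - np.exp(-(np.maximum(edges - self.t0, 0))
                                            / tau), 0.0)
            p = np.diff(cdf)
            s = p.sum()
            if s <= 0:
                raise ValueError("decay model places no mass in the window")
            out.append(p / s)
        return out[0], out[1]


@dataclass(frozen=True)
class DecayFit:
    """Result of a fixed-lifetime two-component fit.

    ``a1``/``a2`` are pre-exponential amplitudes (photons/ns at t0);
    ``n1``/``n2`` are the photon counts attributed to each component
    (``n_i = a_i * tau_i``).  ``f_n`` is the photon fraction of the short
    component, ``a1*tau1 / (a1*tau1 + a2*tau2)``.
    """

    a1: float
    a2: float
    background: float
    tau1: float
    tau2: float

    @property
    def n1(self) -> float:
        return self.a1 * self.tau1

    @property
    def n2(self) -> float:
        return self.a2 * self.tau2

    @property
    def total(self) -> float:
        return self.n1 + self.n2

    @property
    def f_n(self) -> float:
        denom = self.n1 + self.n2
        return self.n1 / denom if denom > 0 else 0.0

    @property
    def f_c(self) -> float:
        return 1.0 - self.f_n


def fit_decay(counts: np.ndarray, model: DecayModel,
              photon_floor: int = 50) -> DecayFit:
    """Poisson maximum-likelihood two-component fit with fixed lifetimes.

    Parameters
    ----------
    counts : array of shape (n_bins,)
        Photon counts per TCSPC bin.
    model : DecayModel
    photon_floor : int
        Minimum total photons; below it the fit is refused.

    Raises
    ------
    InsufficientPhotonsError
        If ``counts.sum() < photon_floor``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (model.n_bins,):
        raise ValueError(f"expected {model.n_bins} bins, got {counts.shape}")
    total = counts.sum()
    if total < photon_floor:
        raise InsufficientPhotonsError(
            f"{total:.0f} photons < floor {photon_floor}")

    p1, p2 = model.component_bin_probabilities()
    nb = model.n_bins

    def nll(theta: np.ndarray) -> float:
        n1, n2, b = theta
        mu = n1 * p1 + n2 * p2 + b / nb
        mu = np.maximum(mu, 1e-12)
        return float(np.sum(mu - counts * np.log(mu)))

    x0 = np.array([0.5 * total, 0.5 * total, 1e-3 * total + 1e-6])
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            bounds=[(0, None)] * 3)
    n1, n2, b = res.x
    return DecayFit(a1=n1 / model.tau1, a2=n2 / model.tau2, background=b,
                    tau1=model.tau1, tau2=model.tau2)


@dataclass
class TerminusImagePair:
    """Per-pixel NT-EEA1 / CT-EEA1 photon images from one FLIM frame."""

    nt_image: np.ndarray
    ct_image: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.nt_image.shape, dtype=bool)

    @property
    def total(self) -> np.ndarray:
        return self.nt_image + self.ct_image


def unmix_frame(stack: np.ndarray, model: DecayModel,
                photon_floor: int = 50, pool_radius: int = 1) -> TerminusImagePair:
    """Split a per-pixel TCSPC stack into NT and CT photon images.

    ``stack`` has shape (ny, nx, n_bins).  Pixels below the photon floor are
    fitted on a pooled ``(2*pool_radius+1)``-square neighbourhood histogram;
    pixels that still lack photons are masked invalid and zero-filled.
    ``nt + ct`` equals the total photon image exactly on valid pixels.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[2] != model.n_bins:
        raise ValueError("stack must be (ny, nx, n_bins)")
    ny, nx, _ = stack.shape
    totals = stack.sum(axis=2).astype(float)
    nt = np.zeros((ny, nx))
    ct = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            tot = totals[iy, ix]
            if tot == 0:
                continue
            hist = stack[iy, ix]
            if tot < photon_floor and pool_radius > 0:
                y0, y1 = max(0, iy - pool_radius), min(ny, iy + pool_radius + 1)
                x0, x1 = max(0, ix - pool_radius), min(nx, ix + pool_radius + 1)
                hist = stack[y0:y1, x0:x1].sum(axis=(0, 1))
            try:
                fit = fit_decay(hist, model, photon_floor=photon_floor)
            except InsufficientPhotonsError:
                continue
            nt[iy, ix] = tot * fit.f_n
            ct[iy, ix] = tot * fit.f_c
            valid[iy, ix] = True
    return TerminusImagePair(nt_image=nt, ct_image=ct, valid=valid)


def moving_average(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; edges use the available samples only."""
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def nc_ratio_trace(nt_sums: np.ndarray, ct_sums: np.ndarray,
                   smoothing_window: int = 3) -> dict[str, np.ndarray]:
    """N:C intensity-ratio trace for one tracked endosome.

    ``nt_sums``/``ct_sums`` are per-frame NT and CT photon sums over the
    endosome mask.  The C channel is floored at one photon before division;
    the smoothed trace is a centered moving average of the given window
    (3 frames by default).
    """
    nt = np.asarray(nt_sums, dtype=float)
    ct = np.asarray(ct_sums, dtype=float)
    if nt.shape != ct.shape or nt.ndim != 1 or nt.size == 0:
        raise ValueError("nt_sums and ct_sums must be equal-length 1-D")
    ratio = nt / np.maximum(ct, 1.0)
    return {
        "n": nt,
        "c": ct,
        "ratio": ratio,
        "ratio_smooth": moving_average(ratio, smoothing_window),
    }


_LABEL_ORDER = {"N": 0, "A": 1, "C": 2}


def classify_endosome(fit: DecayFit, presence_threshold: float = 100.0,
                      n_fraction_cut: float = 0.5) -> str:
    """Label one endosome N / C / A from its decay fit.

    ``A`` (EEA1 absent, Rab5-positive) if total EEA1 photons fall below the
    presence threshold; otherwise ``N`` if the short-component photon
    fraction is at least the cut (0.5 default), else ``C``.
    """
    if fit.total < presence_threshold:
        return "A"
    return "N" if fit.f_n >= n_fraction_cut else "C"


def classify_pair(fit_a: DecayFit, fit_b: DecayFit,
                  presence_threshold: float = 100.0,
                  n_fraction_cut: float = 0.5) -> str:
    """Unordered fusion-pair category (N+A, A+C, N+N, N+C, C+C or A+A)."""
    la = classify_endosome(fit_a, presence_threshold, n_fraction_cut)
    lb = classify_endosome(fit_b, presence_threshold, n_fraction_cut)
    first, second = sorted((la, lb), key=_LABEL_ORDER.__getitem__)
    return f"{first}+{second}"
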