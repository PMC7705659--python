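"""Ks distributions, mixture-model peak finding, rate correction and dating.

A whole-genome duplication leaves a peak in the distribution of Ks values of
surviving duplicate pairs. Peaks are located by fitting Gaussian mixtures to
log(Ks) (i.e. lognormal components on the Ks scale — Ks is positive and
right-skewed), selecting the component count by BIC; the reported peak
location of a component is its median on the Ks scale, exp(mu).

When the focal lineage evolves faster than a reference lineage, its Ks-based
ages are biased high. The correction measures the relative rate from a WGD
event *shared* by both lineages: with the focal peak at k_L and the reference
peak at k_C for the same event, r = (k_L - k_C)/k_C and the correction
coefficient is W_L = 1/(1 + r). Every focal peak (and the between-species
ortholog peak) is rescaled by W_L; rescaled Ks converts to an age via
T = Ks / (2 * rate), with the neutral substitution rate per site per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

DEFAULT_SUBST_RATE = 8.22e-9  # neutral substitutions/site/year


@dataclass
class KsDistribution:
    values: np.ndarray
    source: str = "paralog_L"  # paralog_L | paralog_C | ortholog_LC | other
    filter_bounds: tuple[float, float] = (0.005, 3.0)
    n_excluded_invalid: int = 0
    n_excluded_bounds: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PeakModel:
    """Fitted mixture over log(Ks): (weight, mean, sd) per component."""

    components: list[tuple[float, float, float]]
    model_score: float  # BIC of the selected model (lower is better)
    n_values: int
    method: str = "gmm-log"

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def peak_locations(self) -> list[float]:
        """Component medians back-transformed to the Ks scale, ascending."""
        return sorted(float(np.exp(m)) for _, m, _ in self.components)

    @property
    def weights(self) -> list[float]:
        return [w for w, _, _ in self.components]


@dataclass(frozen=True)
class RateCorrection:
    """Relative-rate correction derived from a shared event's two peaks."""

    k_C: float
    k_L: float
    r: float
    W_L: float

    @classmethod
    def from_peaks(cls, k_C: float, k_L: float) -> "RateCorrection":
        r = relative_rate(k_C, k_L)
        return cls(k_C=k_C, k_L=k_L, r=r, W_L=1.0 / (1.0 + r))


@dataclass(frozen=True)
class WGDEvent:
    """A dated duplication (or divergence) with correction provenance."""

    label: str
    raw_peak: float
    corrected_peak: float
    age_mya: float
    subst_rate: float
    provenance: str = ""


# ------------------------------------------------------------------ pipeline

def build_distribution(
    ks_values: Iterable[float],
    lo: float = 0.005,
    hi: float = 3.0,
    source: str = "other",
) -> KsDistribution:
    """Bound and clean a set of Ks values for peak fitting.

    Non-finite values count as invalid; values outside ``[lo, hi]`` are
    excluded and counted. Fewer than 50 survivors triggers a warning (peak
    fitting is unreliable there) but is not an error.
    """
    arr = np.asarray(list(ks_values), dtype=float)
    finite = np.isfinite(arr)
    in_bounds = finite & (arr >= lo) & (arr <= hi)
    dist = KsDistribution(
        values=np.sort(arr[in_bounds]),
        source=source,
        filter_bounds=(lo, hi),
        n_excluded_invalid=int((~finite).sum()),
        n_excluded_bounds=int((finite & ~in_bounds).sum()),
    )
    if len(dist) < 50:
        warnings.warn(
            f"only {len(dist)} Ks values survive filtering; peak fitting unreliable",
            stacklevel=2,
        )
    return dist


def fit_peaks(
    dist: KsDistribution,
    k_range: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
    n_init: int = 10,
) -> PeakModel:
    """Fit lognormal mixtures by EM and select the component count by BIC.

    The fit is deterministic for a fixed seed (``n_init`` restarts all derive
    from it). Raises if EM fails to converge for every candidate k.
    """
    if len(dist) < 2:
        raise ValueError("need at least 2 values to fit peaks")
    x = np.log(dist.values).reshape(-1, 1)
    best: GaussianMixture | None = None
    best_bic = np.inf
    failures = []
    for k in k_range:
        if k > len(dist):
            continue
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            max_iter=500,
        )
        try:
            gm.fit(x)
        except ValueError as exc:  # pragma: no cover - degenerate inputs
            failures.append(f"k={k}: {exc}")
            continue
        if not gm.converged_:
            failures.append(f"k={k}: EM did not converge")
            continue
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    if best is None:
        raise RuntimeError("EM failed for every component count: " + "; ".join(failures))
    comps = sorted(
        (
            (float(w), float(m), float(np.sqrt(c)))
            for w, m, c in zip(
                best.weights_, best.means_.ravel(), best.covariances_.ravel()
            )
        ),
        key=lambda t: t[1],
    )
    return PeakModel(components=comps, model_score=float(best_bic), n_values=len(dist))


def assign_component(model: PeakModel, ks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior component assignment of Ks values under a fitted mixture.

    Returns ``(labels, posterior)`` where labels index ``model.components``
    (sorted by mean) and posterior is the winning component's responsibility.
    Used to pick 'high-confidence' members of one WGD peak.
    """
    x = np.log(np.asarray(ks, dtype=float))
    logp = np.full((len(x), model.n_components), -np.inf)
    for j, (w, m, s) in enumerate(model.components):
        logp[:, j] = (
            np.log(w) - 0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * ((x - m) / s) ** 2
        )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    labels = p.argmax(axis=1)
    return labels, p[np.arange(len(x)), labels]


def kde_peaks(dist: KsDistribution, bw_method: float | str = "scott") -> list[float]:
    """Alternative peak finder: local maxima of a Gaussian KDE on log(Ks).

    Provided as a cross-check for the mixture fit, not the primary method.
    """
    x = np.log(dist.values)
    kde = gaussian_kde(x, bw_method=bw_method)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    idx = argrelmax(dens)[0]
    return [float(np.exp(grid[i])) for i in idx]


# ------------------------------------------------------------------ arithmetic

def relative_rate(k_C: float, k_L: float) -> float:
    """Relative evolutionary rate r = (k_L - k_C) / k_C of the focal lineage.

    Negative r means the focal lineage is the slower one.
    """
    if k_C <= 0:
        raise ValueError("reference peak k_C must be > 0")
    return (k_L - k_C) / k_C


def correct_ks(k: float, w_l: float) -> float:
    """Rescale a focal-lineage Ks peak by the correction coefficient W_L."""
    if w_l <= 0:
        raise ValueError("W_L must be > 0")
    return w_l * k


def ks_to_time(ks: float, subst_rate: float = DEFAULT_SUBST_RATE) -> float:
    """Age in Mya from Ks via T = Ks / (2 r): unrounded; round at display."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if subst_rate <= 0:
        raise ValueError("subst_rate must be > 0")
    return ks / (2.0 * subst_rate) / 1e6


def date_wgd_events(
    focal_peaks: Mapping[str, float],
    reference_peaks: Mapping[str, float],
    shared_event_pairing: tuple[str, str],
    subst_rate: float = DEFAULT_SUBST_RATE,
    ortholog_peak: float | None = None,
) -> tuple[list[WGDEvent], RateCorrection]:
    """Date every focal WGD peak with rate correction from a shared event.

    ``shared_event_pairing = (focal_label, reference_label)`` declares which
    focal peak and which reference peak mark the *same* (shared) WGD; r and
    W_L are derived from that pair, W_L is applied to every focal peak and,
    if given, to the between-species ortholog peak, and corrected peaks are
    converted to ages. By construction the corrected shared-event peak
    equals the reference peak exactly.
    """
    f_label, r_label = shared_event_pairing
    if f_label not in focal_peaks or r_label not in reference_peaks:
        raise ValueError(
            "shared-event pairing must name one focal and one reference peak"
        )
    corr = RateCorrection.from_peaks(
        k_C=float(reference_peaks[r_label]), k_L=float(focal_peaks[f_label])
    )
    prov = (
        f"r=(k_L-k_C)/k_C=({corr.k_L:g}-{corr.k_C:g})/{corr.k_C:g}={corr.r:g}; "
        f"W_L=1/(1+r)={corr.W_L:g}; shared pairing focal[{f_label}]~ref[{r_label}]"
    )
    events = []
    for label in focal_peaks:
        raw = float(focal_peaks[label])
        corrected = correct_ks(raw, corr.W_L)
        events.append(
            WGDEvent(
                label=label,
                raw_peak=raw,
                corrected_peak=corrected,
                age_mya=ks_to_time(corrected, subst_rate),
                subst_rate=subst_rate,
                provenance=prov + f"; corrected=W_L*{raw:g}",
            )
        )
    if ortholog_peak is not None:
        corrected = correct_ks(float(ortholog_peak), corr.W_L)
        events.append(
            WGDEvent(
                label="divergence",
                raw_peak=float(ortholog_peak),
                corrected_peak=corrected,
                age_mya=ks_to_time(corrected, subst_rate),
                subst_rate=subst_rate,
                provenance=prov + f"; corrected=W_L*{ortholog_peak:g} (ortholog peak)",
            )
        )
    return events, corr


def events_table(events: Sequence[WGDEvent], corr: RateCorrection):
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [e.label for e in events],
            "raw_peak": [e.raw_peak for e in events],
            "corrected_peak": [e.corrected_peak for e in events],
            "age_mya": [round(e.age_mya, 2) for e in events],
            "r": corr.r,
            "W_L": corr.W_L,
        }
    )
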