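"""Quantitative receptor autoradiography: densitometric calibration,
linearization, binding arithmetic and regional receptor fingerprints.

Film autoradiographs encode binding-site density nonlinearly in gray
values.  Co-exposed plastic standards of known radioactivity give a
transformation curve gray → density (fmol/mg protein); applying its
inverse pixelwise ("linearization") yields density images, from which
regional/laminar means are extracted.  A region's fingerprint is the
vector of its mean densities over the 15-receptor panel, with the
standard error of the mean as dispersion.

Quantification always precedes any visualization; contrast enhancement
or smoothing is display-only and never applied before densitometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ReceptorEntry",
    "ReceptorPanel",
    "CalibrationCurve",
    "Fingerprint",
    "BindingResult",
    "fit_calibration",
    "linearize_image",
    "specific_binding",
    "regional_profile",
    "build_fingerprint",
    "compare_fingerprints",
    "plot_fingerprint",
    "write_fingerprint_csv",
    "read_fingerprint_csv",
]


@dataclass(frozen=True)
class ReceptorEntry:
    receptor: str
    transmitter: str
    ligand: str
    concentration_nM: float
    displacer: str

    def __post_init__(self) -> None:
        if self.concentration_nM <= 0:
            raise ValueError("ligand concentration must be positive")


#: The 15-receptor binding panel: tritiated ligand, incubation
#: concentration and displacer per binding site.
CANONICAL_PANEL: tuple = (
    ReceptorEntry("AMPA", "glutamate", "[3H]AMPA", 10.0, "quisqualate"),
    ReceptorEntry("kainate", "glutamate", "[3H]kainate", 9.4, "SYM 2081"),
    ReceptorEntry("NMDA", "glutamate", "[3H]MK-801", 3.3, "(+)MK-801"),
    ReceptorEntry("GABA_A", "GABA", "[3H]muscimol", 7.7, "GABA"),
    ReceptorEntry("GABA_B", "GABA", "[3H]CGP 54626", 2.0, "CGP 55845"),
    ReceptorEntry("GABA_A/BZ", "GABA", "[3H]flumazenil", 1.0, "clonazepam"),
    ReceptorEntry("M1", "acetylcholine", "[3H]pirenzepine", 1.0, "pirenzepine"),
    ReceptorEntry("M2", "acetylcholine", "[3H]oxotremorine-M", 1.7, "carbachol"),
    ReceptorEntry("M3", "acetylcholine", "[3H]4-DAMP", 1.0, "atropine sulfate"),
    ReceptorEntry("nicotinic_a4b2", "acetylcholine", "[3H]epibatidine", 0.5, "nicotine"),
    ReceptorEntry("5-HT1A", "serotonin", "[3H]8-OH-DPAT", 1.0, "5-hydroxytryptamine"),
    ReceptorEntry("5-HT2", "serotonin", "[3H]ketanserin", 1.14, "mianserin"),
    ReceptorEntry("alpha1", "norepinephrine", "[3H]prazosin", 0.2, "phentolamine mesylate"),
    ReceptorEntry("alpha2", "norepinephrine", "[3H]RX 821002", 1.4, "phentolamine mesylate"),
    ReceptorEntry("D1", "dopamine", "[3H]SCH 23390", 1.67, "SKF 83566"),
)


@dataclass(frozen=True)
class ReceptorPanel:
    """Ordered receptor panel; 15 canonical binding sites by default."""

    entries: tuple = CANONICAL_PANEL

    @classmethod
    def canonical(cls) -> "ReceptorPanel":
        return cls(CANONICAL_PANEL)

    @property
    def names(self) -> tuple:
        return tuple(e.receptor for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CalibrationCurve:
    """Fitted monotone transformation between gray value and density.

    ``kind`` is 'saturating_exponential' (parametric fit
    gray = g0 + g_max·(1 − exp(−k·density))) or 'monotone_interpolation'
    (shape-preserving PCHIP through the standards).  ``polarity`` is +1
    when gray increases with density, −1 when it decreases.
    """

    densities: np.ndarray
    grays: np.ndarray
    kind: str
    polarity: int
    params: Optional[dict]
    residual_scale: float
    _gray_to_density: object

    @property
    def gray_domain(self) -> tuple:
        lo, hi = float(np.min(self.grays)), float(np.max(self.grays))
        return lo, hi

    def to_density(self, gray) -> np.ndarray:
        return np.asarray(self._gray_to_density(np.asarray(gray, dtype=float)))


def _fit_saturating_exponential(dens: np.ndarray, gray: np.ndarray, polarity: int):
    g0_guess = gray[0]
    span = gray[-1] - gray[0]

    def model(d, g0, gmax, k):
        return g0 + gmax * (1.0 - np.exp(-k * d))

    drange = dens[-1] - dens[0] if dens[-1] > dens[0] else 1.0
    p0 = (g0_guess, span * 1.2 if span != 0 else polarity, 1.0 / drange)
    popt, _ = optimize.curve_fit(model, dens, gray, p0=p0, maxfev=20000)
    g0, gmax, k = popt
    if gmax * polarity <= 0 or k <= 0:
        raise RuntimeError("fit not monotone in the standard direction")

    def inverse(g):
        x = 1.0 - (np.asarray(g, dtype=float) - g0) / gmax
        return np.clip(-np.log(np.clip(x, 1e-12, None)) / k, 0.0, None)

    resid = gray - model(dens, *popt)
    return inverse, {"g0": float(g0), "g_max": float(gmax), "gain": float(k)}, float(
        np.sqrt(np.mean(resid**2))
    )


def fit_calibration(standards: Sequence, noise_tolerance: float = 0.02) -> CalibrationCurve:
    """Fit the gray ↔ density transformation from co-exposed standards.

    ``standards`` is a sequence of ``(known_density, observed_gray)``
    pairs (≥ 4, distinct densities).  The default fit is a saturating
    exponential; if that fails to converge, a monotone shape-preserving
    interpolation through the standards is used instead.  Standards whose
    gray values are non-monotone in density beyond ``noise_tolerance``
    (fraction of the gray range) raise an error with diagnostics.
    """
    arr = np.asarray([(float(d), float(g)) for d, g in standards], dtype=float)
    if arr.shape[0] < 4:
        raise ValueError("need >= 4 calibration standards")
    order = np.argsort(arr[:, 0])
    dens, gray = arr[order, 0], arr[order, 1]
    if np.any(np.diff(dens) <= 0):
        raise ValueError("standard densities must be distinct")

    span = gray.max() - gray.min()
    if span <= 0:
        raise ValueError("standards have zero gray-value range")
    steps = np.diff(gray)
    polarity = 1 if np.sum(steps) >= 0 else -1
    violation = np.max(np.clip(-polarity * steps, 0, None)) / span
    if violation > noise_tolerance:
        raise ValueError(
            "standards are not monotone beyond noise tolerance: worst reversal "
            f"{violation:.1%} of gray range (tolerance {noise_tolerance:.1%}); "
            f"gray values in density order: {np.round(gray, 2).tolist()}"
        )

    try:
        inverse, params, resid = _fit_saturating_exponential(dens, gray, polarity)
        kind = "saturating_exponential"
    except (RuntimeError, optimize.OptimizeWarning):
        # monotone fallback: isotonic-regularized PCHIP from gray to density
        g_mono = np.maximum.accumulate(polarity * gray)
        keep = np.concatenate([[True], np.diff(g_mono) > 0])
        interp = PchipInterpolator(g_mono[keep], dens[keep], extrapolate=True)

        def inverse(g):
            return np.clip(interp(polarity * np.asarray(g, dtype=float)), 0.0, None)

        params, resid, kind = None, 0.0, "monotone_interpolation"

    return CalibrationCurve(
        densities=dens,
        grays=gray,
        kind=kind,
        polarity=polarity,
        params=params,
        residual_scale=resid,
        _gray_to_density=inverse,
    )


def linearize_image(gray_image: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Convert a gray-value autoradiograph to a density image
    (fmol/mg protein) by pixelwise application of the calibration.

    Gray values outside the standards' range are clipped to it with a
    warning (extrapolating a saturating film response is unreliable).
    """
    gray = np.asarray(gray_image, dtype=float)
    lo, hi = curve.gray_domain
    n_out = int(np.count_nonzero((gray < lo) | (gray > hi)))
    if n_out:
        warnings.warn(
            f"{n_out} pixel(s) outside the calibrated gray range [{lo:.1f}, {hi:.1f}]; clipped"
        )
    return curve.to_density(np.clip(gray, lo, hi))


@dataclass(frozen=True)
class BindingResult:
    specific: np.ndarray
    nsb_fraction: Optional[float]
    negligible: Optional[bool]  # True when nsb_fraction < 0.05


def specific_binding(
    total: np.ndarray,
    nonspecific: Optional[np.ndarray] = None,
    negligible_threshold: float = 0.05,
) -> BindingResult:
    """Specific binding = total − non-specific, floored at zero.

    When the non-specific image is absent, total is taken as specific and
    the fraction is reported missing — the shortcut justified when
    non-specific binding is below 5% of total.  When present, the
    mean-level fraction is computed and flagged if it reaches 5%.
    """
    tot = np.asarray(total, dtype=float)
    if (tot < 0).any():
        raise ValueError("total binding image has negative densities")
    if nonspecific is None:
        return BindingResult(specific=tot.copy(), nsb_fraction=None, negligible=None)
    nsb = np.asarray(nonspecific, dtype=float)
    if nsb.shape != tot.shape:
        raise ValueError("total and non-specific images must share the grid")
    if (nsb < 0).any():
        raise ValueError("non-specific binding image has negative densities")
    frac = float(nsb.mean() / tot.mean()) if tot.mean() > 0 else 0.0
    negligible = frac < negligible_threshold
    if not negligible:
        warnings.warn(
            f"non-specific binding is {frac:.1%} of total (>= {negligible_threshold:.0%}); "
            "total binding must not be used as specific binding"
        )
    return BindingResult(specific=np.clip(tot - nsb, 0.0, None), nsb_fraction=frac, negligible=negligible)


def regional_profile(density_image: np.ndarray, masks: Mapping) -> pd.DataFrame:
    """Pixel-count-weighted mean density per labeled compartment.

    ``masks`` maps a key — a region code or a (region, layer) tuple — to
    a boolean mask on the image grid.  Masks must be pairwise disjoint.
    Empty masks yield NaN with ``missing=True``.
    """
    img = np.asarray(density_image, dtype=float)
    cover = np.zeros(img.shape, dtype=int)
    rows = []
    for key, mask in masks.items():
        m = np.asarray(mask, dtype=bool)
        if m.shape != img.shape:
            raise ValueError(f"mask {key!r} does not match the image grid")
        cover += m
        n = int(m.sum())
        rows.append(
            {
                "key": key,
                "n_pixels": n,
                "mean_density": float(img[m].mean()) if n else np.nan,
                "missing": n == 0,
            }
        )
    if (cover > 1).any():
        raise ValueError("masks must be pairwise disjoint")
    return pd.DataFrame(rows)


def region_mean(profile: pd.DataFrame, weighted: bool = True) -> float:
    """Collapse a multi-layer profile to one regional mean.

    Pixel-count weighting (default) equals direct averaging over all of
    the region's pixels; ``weighted=False`` averages the layer means.
    """
    p = profile[~profile["missing"]]
    if p.empty:
        raise ValueError("no non-empty compartments")
    if weighted:
        return float(np.average(p["mean_density"], weights=p["n_pixels"]))
    return float(p["mean_density"].mean())


@dataclass
class Fingerprint:
    """Mean densities of the receptor panel in one region, with SEM."""

    region_code: int
    densities: np.ndarray
    sem: np.ndarray
    n: int
    panel: ReceptorPanel = field(default_factory=ReceptorPanel.canonical)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if len(self.densities) != len(self.panel) or len(self.sem) != len(self.panel):
            raise ValueError(f"fingerprint must have {len(self.panel)} entries in panel order")
        if (self.densities < 0).any() or (self.sem < 0).any():
            raise ValueError("densities and SEM must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def size(self) -> float:
        """Overall magnitude: mean density over the panel."""
        return float(self.densities.mean())


def build_fingerprint(
    per_subject_densities,
    region_code: int,
    panel: Optional[ReceptorPanel] = None,
) -> Fingerprint:
    """Aggregate per-subject regional densities into a fingerprint.

    ``per_subject_densities`` is an (n_subjects, n_receptors) array or a
    DataFrame with receptor columns in panel order.  Missing values are
    allowed per subject; a receptor missing for every subject raises an
    error naming it.  SEM uses the n−1 sample sd over subjects; with a
    single subject the SEM is 0 by convention (flagged by n = 1).
    """
    panel = panel or ReceptorPanel.canonical()
    if isinstance(per_subject_densities, pd.DataFrame):
        arr = per_subject_densities.reindex(columns=list(panel.names)).to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(per_subject_densities, dtype=float))
    if arr.shape[1] != len(panel):
        raise ValueError(f"expected {len(panel)} receptor columns, got {arr.shape[1]}")
    counts = np.sum(~np.isnan(arr), axis=0)
    dead = [panel.names[i] for i in np.flatnonzero(counts == 0)]
    if dead:
        raise ValueError(f"receptor(s) missing for all subjects: {dead}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=0)
        sds = np.nanstd(arr, axis=0, ddof=1)
    sem = np.where(counts > 1, sds / np.sqrt(counts), 0.0)
    return Fingerprint(
        region_code=region_code,
        densities=means,
        sem=np.nan_to_num(sem),
        n=int(arr.shape[0]),
        panel=panel,
    )


def compare_fingerprints(a: Fingerprint, b: Fingerprint) -> tuple:
    """Size difference and shape distance between two fingerprints.

    Size difference is the difference of panel-mean densities; shape
    distance is the Euclidean distance between the unit-mean-scaled
    vectors, so a pure rescaling has shape distance 0.  Both are package
    conventions for "differently sized / differently shaped" profiles.
    """
    if a.panel.names != b.panel.names:
        raise ValueError("fingerprints use different receptor panels")
    size_difference = a.size - b.size
    if a.size <= 0 or b.size <= 0:
        raise ValueError("shape comparison undefined for zero-mean fingerprints")
    shape_distance = float(np.linalg.norm(a.densities / a.size - b.densities / b.size))
    return size_difference, shape_distance


def plot_fingerprint(fingerprint: Fingerprint, ax=None, label: Optional[str] = None):
    """Polar-plot a fingerprint (mean ring plus ±SEM dashed rings)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = len(fingerprint.panel)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    closed = lambda v: np.concatenate([v, v[:1]])
    th = closed(theta)
    ax.plot(th, closed(fingerprint.densities), label=label)
    ax.fill(th, closed(fingerprint.densities), alpha=0.2)
    if fingerprint.n > 1:
        ax.plot(th, closed(fingerprint.densities + fingerprint.sem), "--", linewidth=0.8)
        ax.plot(th, closed(np.clip(fingerprint.densities - fingerprint.sem, 0, None)), "--", linewidth=0.8)
    ax.set_xticks(theta)
    ax.set_xticklabels(fingerprint.panel.names, fontsize=7)
    return ax


def write_fingerprint_csv(fingerprint: Fingerprint, path) -> None:
    df = pd.DataFrame(
        {
            "receptor": fingerprint.panel.names,
            "mean_density_fmol_mg": fingerprint.densities,
            "sem": fingerprint.sem,
        }
    )
    df.insert(0, "region_code", fingerprint.region_code)
    df.insert(1, "n_subjects", fingerprint.n)
    df.to_csv(path, index=False)


def read_fingerprint_csv(path, panel: Optional[ReceptorPanel] = None) -> Fingerprint:
    df = pd.read_csv(path)
    panel = panel or ReceptorPanel.canonical()
    if list(df["receptor"]) != list(panel.names):
        raise ValueError("fingerprint CSV receptor order does not match the panel")
    return Fingerprint(
        region_code=int(df["region_code"].iloc[0]),
        densities=df["mean_density_fmol_mg"].to_numpy(),
        sem=df["sem"].to_numpy(),
        n=int(df["n_subjects"].iloc[0]),
        panel=panel,
    )
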