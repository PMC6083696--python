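"""Amplitude-mode-model (AMM) frequency-dispersion analysis.

In a sample containing a distribution of chromophores with different
effective conjugation lengths, tuning the excitation energy E_L into
resonance selects sub-populations whose vibrational frequencies differ,
so band centers shift with E_L (frequency dispersion).  The AMM
condenses this into the product rule

    prod_n (ν̃nR / ν̃0R)² = 2λ̄ ,

taken over the dispersing modes, where ν̃0R is the band wavenumber at
the lowest excitation energy used and λ̄ is an effective
electron–phonon coupling constant, and into the dispersion rate

    D = Δ prod_n (ν̃nR / ν̃0R)² / Δ E_L ,

the slope of 2λ̄ against excitation energy.  D near zero means a
single chromophore; large D means coupled/heterogeneous chromophores.
D carries units of cm when E_L is in cm⁻¹ and eV⁻¹ when E_L is in eV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .peakfit import BAND_WINDOWS, BandTrack
from .units import CM_PER_EV, invcm_to_eV, nm_to_invcm

__all__ = [
    "HueRecord",
    "RegressionResult",
    "DispersionFit",
    "SIGNIFICANT_SHIFT_CM",
    "ratio_squared",
    "amm_product",
    "fit_dispersion",
    "tracks_from_table",
    "hue_trend",
]

#: Spectral variations larger than this (cm⁻¹) exceed the combined
#: spectral + calibration resolution and are considered sample-related.
SIGNIFICANT_SHIFT_CM: float = 3.0

HUE_ORDER: tuple[str, ...] = ("magenta", "red", "orange", "yellow")


@dataclass
class HueRecord:
    """Doublet positions for one specimen with an ordered hue label."""

    specimen_id: str
    hue: str
    nu_cc: float
    nu_cc2: float

    def __post_init__(self) -> None:
        if self.hue not in HUE_ORDER:
            raise ValidationError(f"hue must be one of {HUE_ORDER}, got {self.hue!r}")
        lo, hi = BAND_WINDOWS["cc"]
        if not lo <= self.nu_cc <= hi:
            raise ValidationError(f"nu_cc {self.nu_cc} outside window ({lo}, {hi})")
        lo, hi = BAND_WINDOWS["cc2"]
        if not lo <= self.nu_cc2 <= hi:
            raise ValidationError(f"nu_cc2 {self.nu_cc2} outside window ({lo}, {hi})")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


@dataclass
class DispersionFit:
    """Full AMM output for one excitation series."""

    tracks: list[BandTrack]
    energy_invcm: np.ndarray
    products: np.ndarray                      # 2λ̄ per included excitation
    per_band: dict[str, RegressionResult]
    product_fit: RegressionResult
    D_cm: float
    D_eV: float
    fit_error_pct: float | None               # 100·SE(slope)/|slope|; None if D ~ 0
    max_shift_per_band: dict[str, float]
    significant: bool
    energy_axis: str = "invcm"
    fit_error_definition: str = "100 * SE(product slope) / |product slope|"

    @property
    def product_R2(self) -> float:
        return self.product_fit.r_squared

    @property
    def product_p(self) -> float:
        return self.product_fit.p_value

    @property
    def n_points(self) -> int:
        return self.product_fit.n

    def summary(self) -> str:
        lines = [
            f"AMM dispersion fit ({self.n_points} excitations)",
            f"  D = {self.D_cm:.4g} cm  ({self.D_eV:.4g} eV^-1)",
            f"  product rule: R^2 = {self.product_R2:.3f}, p = {self.product_p:.3g}",
            "  fit error = " + (f"{self.fit_error_pct:.1f}%" if self.fit_error_pct
                                is not None else "n/a (|D| ~ 0)"),
        ]
        for band, reg in self.per_band.items():
            lines.append(
                f"  {band}: slope {reg.slope:.4g}, R^2 = {reg.r_squared:.3f}, "
                f"p = {reg.p_value:.3g}, range {self.max_shift_per_band[band]:.2f} cm^-1")
        lines.append(
            f"  dispersion {'significant' if self.significant else 'not significant'} "
            f"(> {SIGNIFICANT_SHIFT_CM:g} cm^-1 band-shift threshold)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "energy_axis": self.energy_axis,
            "D_cm": self.D_cm,
            "D_eV": self.D_eV,
            "fit_error_pct": self.fit_error_pct,
            "fit_error_definition": self.fit_error_definition,
            "product_R2": self.product_R2,
            "product_p": self.product_p,
            "products": self.products.tolist(),
            "energy_invcm": self.energy_invcm.tolist(),
            "per_band": {
                b: {"slope": r.slope, "intercept": r.intercept,
                    "R2": r.r_squared, "p": r.p_value, "stderr": r.stderr,
                    "max_shift_cm": self.max_shift_per_band[b]}
                for b, r in self.per_band.items()},
            "significant": self.significant,
            "significance_threshold_cm": SIGNIFICANT_SHIFT_CM,
            "excluded": {b: t.excluded for b, t in
                         zip(self.per_band, self.tracks)},
        }


def ratio_squared(track: BandTrack) -> np.ndarray:
    """Per-excitation (ν̃nR / ν̃0R)²; exactly 1 at the reference."""
    if track.ref_center <= 0:
        raise ValidationError("reference wavenumber must be positive")
    return (track.centers / track.ref_center) ** 2


def _check_aligned(tracks: Sequence[BandTrack]) -> None:
    ref = tracks[0]
    for t in tracks[1:]:
        if t.excitation_nm.size != ref.excitation_nm.size or not np.allclose(
                t.excitation_nm, ref.excitation_nm):
            a = set(np.round(ref.excitation_nm, 6))
            b = set(np.round(t.excitation_nm, 6))
            raise ValidationError(
                f"tracks cover different excitation sets; difference: {sorted(a ^ b)}")
        if abs(t.ref_excitation_nm - ref.ref_excitation_nm) > 1e-6:
            raise ValidationError("tracks disagree on the reference excitation")


def amm_product(tracks: Sequence[BandTrack]) -> np.ndarray:
    """Product-rule 2λ̄ per excitation: elementwise product of
    (ν̃nR/ν̃0R)² over all dispersing bands."""
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("no tracks given")
    _check_aligned(tracks)
    out = np.ones_like(tracks[0].centers, dtype=float)
    for t in tracks:
        out = out * ratio_squared(t)
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in excitation energy")
    if np.ptp(y) == 0:
        # flat response: slope identically 0, nothing to explain
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, 0.0, x.size)
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue) ** 2, float(res.pvalue),
                            float(res.stderr), x.size)


def fit_dispersion(tracks: Sequence[BandTrack], energy_axis: str = "invcm") -> DispersionFit:
    """OLS of the product-rule values on excitation energy → D.

    Per-band regressions of (ν̃nR/ν̃0R)² on E_L are reported alongside.
    R² and p are invariant to the energy axis; the slope is reported in
    both unit systems (D_eV = D_cm × 8065.544).  The ``significant``
    flag is set when any band's center range exceeds the 3 cm⁻¹
    resolution threshold.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("no tracks given")
    _check_aligned(tracks)
    if len(tracks[0]) < 3:
        raise InsufficientDataError("need >= 3 included excitations")
    if energy_axis not in ("invcm", "eV"):
        raise ValidationError(f"energy_axis must be 'invcm' or 'eV', got {energy_axis!r}")

    e_invcm = tracks[0].energy_invcm
    x = e_invcm if energy_axis == "invcm" else tracks[0].energy_eV
    products = amm_product(tracks)
    product_fit = _ols(x, products)
    per_band = {t.band: _ols(x, ratio_squared(t)) for t in tracks}

    slope = product_fit.slope
    if energy_axis == "invcm":
        D_cm, D_eV = slope, slope * CM_PER_EV
    else:
        D_cm, D_eV = slope / CM_PER_EV, slope
    assert abs(D_eV - D_cm * CM_PER_EV) <= 1e-9 * max(abs(D_eV), 1e-300)

    fit_error = (100.0 * product_fit.stderr / abs(slope)
                 if abs(slope) > 1e-15 else None)
    shifts = {t.band: t.max_shift for t in tracks}
    return DispersionFit(
        tracks=tracks, energy_invcm=e_invcm, products=products,
        per_band=per_band, product_fit=product_fit,
        D_cm=D_cm, D_eV=D_eV, fit_error_pct=fit_error,
        max_shift_per_band=shifts,
        significant=any(v > SIGNIFICANT_SHIFT_CM for v in shifts.values()),
        energy_axis=energy_axis,
    )


def tracks_from_table(
    table: pd.DataFrame,
    bands: Sequence[str] = ("cc", "cc2"),
    exclusions: Sequence[float] | Mapping[float, str] = (),
) -> list[BandTrack]:
    """Build band tracks from a measured peak table.

    ``table`` needs columns ``band``, ``excitation_nm``, ``center``
    (cm⁻¹) — the form in which excitation-series peak positions are
    published or exported by the ``peaks`` command.  Exclusions are
    applied before the reference excitation is chosen.
    """
    for col in ("band", "excitation_nm", "center"):
        if col not in table.columns:
            raise ValidationError(f"peak table lacks column {col!r}")
    if isinstance(exclusions, Mapping):
        reasons = {float(k): str(v) for k, v in exclusions.items()}
    else:
        reasons = {float(nm): "user" for nm in exclusions}

    tracks = []
    for band in bands:
        sub = table[table["band"] == band]
        if sub.empty:
            raise ValidationError(f"peak table has no rows for band {band!r}")
        nm = sub["excitation_nm"].to_numpy(dtype=float)
        centers = sub["center"].to_numpy(dtype=float)
        keep = np.array([not any(abs(v - x) < 1e-6 for x in reasons) for v in nm])
        excluded = [(float(v), reasons[min(reasons, key=lambda x: abs(x - v))])
                    for v in nm[~keep]]
        nm, centers = nm[keep], centers[keep]
        if nm.size < 3:
            raise InsufficientDataError(
                f"band {band!r}: only {nm.size} excitations after exclusion")
        order = np.argsort(-nm)  # ascending energy
        nm, centers = nm[order], centers[order]
        window = BAND_WINDOWS.get(band, (float(centers.min()) - 1.0,
                                         float(centers.max()) + 1.0))
        e = nm_to_invcm(nm)
        tracks.append(BandTrack(
            band=band, excitation_nm=nm, energy_invcm=e,
            energy_eV=invcm_to_eV(e), centers=centers,
            ref_center=float(centers[0]), ref_excitation_nm=float(nm[0]),
            window=window, excluded=excluded))
    return tracks


def hue_trend(records: Sequence[HueRecord]) -> dict:
    """Hue-ordered summary of doublet positions across a feather panel.

    Hues are ranked magenta=1 < red=2 < orange=3 < yellow=4; the
    Spearman rank correlation (average ranks on ties) between hue rank
    and each band position quantifies the tendency of band wavenumbers
    to rise toward yellow.  Returns per-hue median/min/max per band and
    (rho, p) per band.
    """
    records = list(records)
    hues = {r.hue for r in records}
    if len(hues) < 2:
        raise DegenerateInputError("hue trend needs >= 2 hue categories")
    df = pd.DataFrame({
        "specimen_id": [r.specimen_id for r in records],
        "hue": [r.hue for r in records],
        "hue_rank": [HUE_ORDER.index(r.hue) + 1 for r in records],
        "nu_cc": [r.nu_cc for r in records],
        "nu_cc2": [r.nu_cc2 for r in records],
    })
    per_hue = (df.groupby("hue")[["nu_cc", "nu_cc2"]]
                 .agg(["median", "min", "max"])
                 .reindex([h for h in HUE_ORDER if h in hues]))
    out = {"per_hue": per_hue, "n": len(records)}
    for band in ("nu_cc", "nu_cc2"):
        if np.ptp(df[band].to_numpy()) == 0:
            rho, p = 0.0, 1.0  # all tied: average ranks carry no ordering
        else:
            rho, p = stats.spearmanr(df["hue_rank"], df[band])
        out[band] = {"spearman_rho": float(rho), "p_value": float(p)}
    return out
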