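"""Activity scoring for the oxime-MSI aminotransferase screen.

The screen's statistic is the fractional conversion ratio

    r = I_product / (I_product + I_acceptor)

computed per spot from the oxime-conjugate ion intensities of the
transamination product and of the residual keto acceptor.  Because both
ions share a spot's desorption/ionization efficiency, the ratio cancels
the dominant spatial variability of the surface.  A donor/acceptor
combination is called active when its replicate-mean ratio is > 0.1 and
more than 10 control standard deviations above the matched no-donor
control; assay quality per hit is summarized by the Z-factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .chem import AdductTarget
from .simulate import CONTROL, PlateDesign

__all__ = [
    "ConversionRecord",
    "HitCall",
    "DoseResponseFit",
    "fractional_conversion",
    "control_stats",
    "call_hits",
    "z_factor",
    "dose_response_fit",
    "summarize_screen",
    "records_from_intensities",
    "hit_table",
]


class InsufficientControlsError(ValueError):
    pass


@dataclass
class ConversionRecord:
    well_id: str
    enzyme: str
    donor: str
    acceptor: str
    replicate: int
    I_product: float
    I_acceptor: float
    ratio: float  # NaN when undefined
    evaluable: bool = True
    note: str = ""


@dataclass
class HitCall:
    enzyme: str
    donor: str
    acceptor: str
    mean_ratio: float
    ratio_sd: float
    n_replicates: int
    control_mean: float
    control_sd: float
    passes_ratio_threshold: bool
    passes_sd_threshold: bool
    active: bool
    z_factor: float = math.nan
    per_replicate_passes: int = 0
    evaluable: bool = True
    reason: str = ""


@dataclass
class DoseResponseFit:
    vmax: float
    km: float
    r_squared: float
    residuals: np.ndarray
    vmax_se: float = math.nan
    km_se: float = math.nan
    flagged: bool = False
    message: str = ""


def fractional_conversion(I_product: float, I_acceptor: float) -> float:
    """Product intensity over total conjugate intensity.

    Scale-invariant: multiplying both intensities by a common factor
    (e.g. the spot's ionization efficiency) leaves the ratio unchanged.
    Both-zero input is undefined and returned as NaN, never as 0.
    """
    if I_product < 0 or I_acceptor < 0:
        raise ValueError("intensities must be non-negative")
    total = I_product + I_acceptor
    if total == 0:
        return math.nan
    return I_product / total


def control_stats(records: list[ConversionRecord]) -> tuple[float, float, int]:
    """Sample mean and SD (n-1 denominator) of control ratios.

    Undefined ratios are dropped with a warning; fewer than two usable
    controls is an error, since the 10-SD rule would be meaningless.
    """
    ratios = [r.ratio for r in records if not math.isnan(r.ratio)]
    n_dropped = len(records) - len(ratios)
    if n_dropped:
        warnings.warn(f"{n_dropped} control replicate(s) with undefined ratio dropped")
    if len(ratios) < 2:
        raise InsufficientControlsError(
            f"need >= 2 evaluable control replicates, have {len(ratios)}"
        )
    arr = np.asarray(ratios)
    return float(arr.mean()), float(arr.std(ddof=1)), len(ratios)


def z_factor(positive_ratios, negative_ratios) -> float:
    """Screening-window coefficient 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|.

    Computed with sample SDs.  1 at zero variance; can be negative for a
    poor assay; undefined (NaN, with warning) when the means coincide.
    """
    pos = np.asarray(list(positive_ratios), dtype=float)
    neg = np.asarray(list(negative_ratios), dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 replicates on each side")
    delta = abs(pos.mean() - neg.mean())
    if delta == 0:
        warnings.warn("Z-factor undefined: positive and negative means coincide")
        return math.nan
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / delta


def records_from_intensities(
    intensities: pd.DataFrame,
    design: PlateDesign,
    targets: list[AdductTarget],
    amounts: pd.DataFrame | None = None,
) -> list[ConversionRecord]:
    """Join an extracted intensity table with the plate design.

    ``intensities`` is tidy (well_id, target, intensity) as produced by
    :func:`oximsi.msi.extract_spot_intensities`, or already-reduced with
    I_product/I_acceptor columns (the simulation shortcut).  For control
    wells — which contain no amino donor and hence no product channel of
    their own — I_product is the mean intensity over all non-degenerate
    product channels of the panel, i.e. pure background.
    """
    product_by_donor = {t.donor_name: t for t in targets if t.role == "product"}
    acceptor_by_name = {t.source_compound.name: t for t in targets if t.role == "acceptor"}

    eval_map: dict[str, tuple[bool, str]] = {}
    if amounts is not None:
        for row in amounts.itertuples(index=False):
            eval_map[row.well_id] = (bool(row.evaluable), row.note)

    if {"I_product", "I_acceptor"}.issubset(intensities.columns):
        wide = intensities.set_index("well_id")
        records = []
        for w in design.wells.itertuples(index=False):
            ip = float(wide.loc[w.well_id, "I_product"])
            ia = float(wide.loc[w.well_id, "I_acceptor"])
            evaluable, note = eval_map.get(w.well_id, (True, ""))
            records.append(
                ConversionRecord(
                    w.well_id, w.enzyme, w.donor, w.acceptor, w.replicate,
                    ip, ia, fractional_conversion(ip, ia), evaluable, note,
                )
            )
        return records

    table = intensities.pivot(index="well_id", columns="target", values="intensity")
    records = []
    for w in design.wells.itertuples(index=False):
        acc_t = acceptor_by_name[w.acceptor]
        ia = float(table.loc[w.well_id, acc_t.name])
        evaluable, note = eval_map.get(w.well_id, (True, ""))
        if w.donor == CONTROL:
            # background: average over product channels that do not collide
            # with any acceptor channel of the panel
            acceptor_mzs = [t.conjugate_mz for t in acceptor_by_name.values()]
            cols = [
                t.name
                for t in product_by_donor.values()
                if all(abs(t.conjugate_mz - amz) > 0.05 for amz in acceptor_mzs)
            ]
            ip = float(table.loc[w.well_id, cols].mean())
        elif w.donor not in product_by_donor:
            ip = math.nan
            if amounts is None:
                evaluable, note = False, "no_product_channel"
        else:
            prod_t = product_by_donor[w.donor]
            ip = float(table.loc[w.well_id, prod_t.name])
            if amounts is None:
                degen = any(
                    c.degenerate and c.other.source_compound.name == w.acceptor
                    for c in prod_t.collisions
                )
                if degen:
                    evaluable, note = False, "degenerate_pair"
        records.append(
            ConversionRecord(
                w.well_id, w.enzyme, w.donor, w.acceptor, w.replicate,
                ip, ia, fractional_conversion(ip, ia), evaluable, note,
            )
        )
    return records


def call_hits(
    records: list[ConversionRecord],
    ratio_threshold: float = 0.1,
    sd_multiplier: float = 10.0,
    min_replicates: int = 2,
) -> list[HitCall]:
    """Dual-threshold hit calling per (enzyme, donor, acceptor).

    The replicate-mean ratio must be strictly above ``ratio_threshold``
    AND strictly above control_mean + sd_multiplier x control_sd, with
    controls matched per (enzyme, acceptor).  Not-evaluable combinations
    (degenerate channels) are reported with a reason, not silently
    dropped; combinations with too few evaluable replicates are reported
    as missing rather than inactive.
    """
    df = pd.DataFrame(
        {
            "enzyme": [r.enzyme for r in records],
            "donor": [r.donor for r in records],
            "acceptor": [r.acceptor for r in records],
            "ratio": [r.ratio for r in records],
            "evaluable": [r.evaluable for r in records],
            "note": [r.note for r in records],
        }
    )
    controls: dict[tuple[str, str], tuple[float, float, int]] = {}
    control_ratios: dict[tuple[str, str], np.ndarray] = {}
    for (enzyme, acceptor), grp in df[df.donor == CONTROL].groupby(["enzyme", "acceptor"]):
        recs = [r for r in records if r.enzyme == enzyme and r.acceptor == acceptor and r.donor == CONTROL]
        controls[(enzyme, acceptor)] = control_stats(recs)
        control_ratios[(enzyme, acceptor)] = grp["ratio"].dropna().to_numpy()

    calls = []
    cond = df[df.donor != CONTROL]
    for (enzyme, donor, acceptor), grp in cond.groupby(["enzyme", "donor", "acceptor"], sort=False):
        key = (enzyme, acceptor)
        if key not in controls:
            raise InsufficientControlsError(f"no control wells for {key}")
        c_mean, c_sd, _ = controls[key]
        if not grp["evaluable"].any():
            notes = [n for n in grp["note"] if n]
            calls.append(
                HitCall(enzyme, donor, acceptor, math.nan, math.nan, 0,
                        c_mean, c_sd, False, False, False,
                        evaluable=False, reason=notes[0] if notes else "not_evaluable")
            )
            continue
        ratios = grp.loc[grp["evaluable"], "ratio"].dropna().to_numpy()
        if len(ratios) < min_replicates:
            calls.append(
                HitCall(enzyme, donor, acceptor, math.nan, math.nan, len(ratios),
                        c_mean, c_sd, False, False, False,
                        evaluable=False, reason="insufficient_replicates")
            )
            continue
        mean = float(ratios.mean())
        sd = float(ratios.std(ddof=1))
        cutoff = c_mean + sd_multiplier * c_sd
        pass_ratio = mean > ratio_threshold
        pass_sd = mean > cutoff
        active = pass_ratio and pass_sd
        per_rep = int(np.sum((ratios > ratio_threshold) & (ratios > cutoff)))
        zf = math.nan
        if active and len(ratios) >= 2:
            neg = control_ratios[key]
            if len(neg) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    zf = z_factor(ratios, neg)
        calls.append(
            HitCall(enzyme, donor, acceptor, mean, sd, len(ratios),
                    c_mean, c_sd, pass_ratio, pass_sd, active,
                    z_factor=zf, per_replicate_passes=per_rep)
        )
    return calls


def hit_table(calls: list[HitCall]) -> pd.DataFrame:
    """Tidy results table, one row per enzyme x donor x acceptor."""
    return pd.DataFrame([vars(c) for c in calls])


def summarize_screen(calls: list[HitCall]) -> dict:
    """Per-enzyme substrate-spectrum summary.

    Counts donors active with >= 1 acceptor and acceptors active with
    >= 1 donor, and returns the donor x acceptor activity matrix.
    """
    df = hit_table(calls) if calls else pd.DataFrame(
        columns=["enzyme", "donor", "acceptor", "active"]
    )
    out = {}
    for enzyme, grp in df.groupby("enzyme"):
        active = grp[grp["active"]]
        matrix = grp.pivot_table(
            index="donor", columns="acceptor", values="active",
            aggfunc="any", fill_value=False,
        )
        out[enzyme] = {
            "n_active_donors": int(active["donor"].nunique()),
            "n_active_acceptors": int(active["acceptor"].nunique()),
            "active_donors": sorted(active["donor"].unique()),
            "active_acceptors": sorted(active["acceptor"].unique()),
            "matrix": matrix,
        }
    return out


def _hyperbola(x, vmax, km):
    return vmax * x / (km + x)


def dose_response_fit(concentrations, ratios) -> DoseResponseFit:
    """Least-squares hyperbolic (Michaelis-Menten form) titration fit.

    Fits r = Vmax * x / (Km + x) to fractional-conversion ratios over a
    donor titration.  Initialization: Vmax0 = max(y), Km0 = x at
    half-max; Vmax bounded to [0, 1.5], Km > 0.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ratios, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if x.min() > 0.1 * x.max():
        warnings.warn("titration lacks a near-zero concentration anchor")
    ymax = float(y.max())
    if ymax <= 0:
        return DoseResponseFit(0.0, math.nan, math.nan, y - 0.0, flagged=True,
                               message="all ratios <= 0; no response")
    half = ymax / 2.0
    km0 = float(x[np.argmin(np.abs(y - half))])
    km0 = max(km0, 1e-6)
    try:
        popt, pcov = curve_fit(
            _hyperbola, x, y, p0=[ymax, km0],
            bounds=([0.0, 1e-9], [1.5, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"hyperbolic fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    resid = y - _hyperbola(x, vmax, km)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan, math.nan]
    return DoseResponseFit(vmax, km, r2, resid,
                           vmax_se=float(ses[0]), km_se=float(ses[1]))
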