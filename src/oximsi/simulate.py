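"""Synthetic arrayed-MSI data with known ground truth.

Emulates the acoustically printed NIMS plate experiment: each well of a
384-well transamination screen is deposited as a cluster of three
replicate spots at 900 um pitch and imaged at a 75 um raster step.  Every
spot carries two informative ion channels — the oxime conjugate of the
well's transamination product and of its residual keto acceptor — whose
amounts follow the planted fractional conversion, plus a uniform baseline
at every panel channel.  A log-normal per-spot efficiency factor shared by
all ions in a spot models desorption/ionization variability across the
surface; the fractional-conversion ratio is insensitive to it by
construction, which is the statistical point of the assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import AdductTarget, degenerate_acceptors
from .dataset import MSIDataset

__all__ = [
    "PlateDesign",
    "TruthProfile",
    "NoiseModel",
    "make_design",
    "ion_amounts",
    "render",
    "simulate_intensities",
    "CONTROL",
    "SPOT_FWHM_PX",
]

CONTROL = "none"  # donor label of no-amino-donor control wells

#: Gaussian spot footprint full width at half maximum, in pixels.
#: For a 10 nl acoustic deposition this corresponds to a ~225 um spot at
#: a 75 um raster step, giving >= 9 informative pixels per spot.
SPOT_FWHM_PX = 3.0
SPOT_SIGMA_PX = SPOT_FWHM_PX / (2.0 * math.sqrt(2.0 * math.log(2.0)))
RENDER_HALFWIDTH_PX = 4  # footprint window half-width; > 3 sigma


class DesignError(ValueError):
    pass


@dataclass
class PlateDesign:
    """Well-to-condition map plus expected spot geometry on the surface.

    ``wells`` has one row per printed spot: well_id, enzyme, donor
    (:data:`CONTROL` for no-donor controls), acceptor, replicate,
    cluster, exp_row, exp_col (0-based expected pixel center).
    """

    wells: pd.DataFrame
    shape: tuple[int, int]
    pitch_um: float = 900.0
    pixel_size_um: float = 75.0
    replicates: int = 3

    @property
    def pitch_px(self) -> int:
        return int(round(self.pitch_um / self.pixel_size_um))

    def conditions(self) -> pd.DataFrame:
        """One row per (enzyme, donor, acceptor) cluster."""
        return self.wells.drop_duplicates(["enzyme", "donor", "acceptor"])[
            ["enzyme", "donor", "acceptor", "cluster"]
        ].reset_index(drop=True)


def make_design(
    enzymes: list[str],
    donors: list[str],
    acceptors: list[str],
    replicates: int = 3,
    pitch_um: float = 900.0,
    pixel_size_um: float = 75.0,
    clusters_per_row: int | None = None,
    max_shape: tuple[int, int] | None = None,
) -> PlateDesign:
    """Lay out a screen: donor x acceptor clusters plus per-acceptor controls.

    Clusters of ``replicates`` adjacent spots are placed row-major on a
    regular grid; each (enzyme, acceptor) group gets one no-donor control
    cluster.  Deterministic for fixed inputs.
    """
    if not enzymes or not donors or not acceptors or replicates < 1:
        raise DesignError("need at least one enzyme, donor, acceptor and replicate")
    clusters: list[tuple[str, str, str]] = []
    for enzyme in enzymes:
        for acceptor in acceptors:
            for donor in donors:
                clusters.append((enzyme, donor, acceptor))
        for acceptor in acceptors:
            clusters.append((enzyme, CONTROL, acceptor))

    n_clusters = len(clusters)
    pitch_px = int(round(pitch_um / pixel_size_um))
    if clusters_per_row is None:
        clusters_per_row = max(1, math.ceil(math.sqrt(n_clusters)))
    n_cluster_rows = math.ceil(n_clusters / clusters_per_row)

    cell_w = (replicates + 1) * pitch_px
    cell_h = 2 * pitch_px
    margin = pitch_px
    n_rows = 2 * margin + (n_cluster_rows - 1) * cell_h + 1
    n_cols = 2 * margin + (clusters_per_row - 1) * cell_w + (replicates - 1) * pitch_px + 1
    if max_shape is not None and (n_rows > max_shape[0] or n_cols > max_shape[1]):
        raise DesignError(
            f"layout capacity exceeded: need {(n_rows, n_cols)}, have {max_shape}"
        )

    rows = []
    for k, (enzyme, donor, acceptor) in enumerate(clusters):
        cr, cc = divmod(k, clusters_per_row)
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "well_id": f"{enzyme}|{donor}|{acceptor}|r{rep}",
                    "enzyme": enzyme,
                    "donor": donor,
                    "acceptor": acceptor,
                    "replicate": rep,
                    "cluster": k,
                    "exp_row": margin + cr * cell_h,
                    "exp_col": margin + cc * cell_w + (rep - 1) * pitch_px,
                }
            )
    return PlateDesign(
        wells=pd.DataFrame(rows),
        shape=(n_rows, n_cols),
        pitch_um=pitch_um,
        pixel_size_um=pixel_size_um,
        replicates=replicates,
    )


@dataclass
class TruthProfile:
    """Planted activity: fraction of donor molecules transaminated.

    ``conversion`` maps (enzyme, donor, acceptor) to the true converted
    fraction f of the donor pool; combinations absent from the map are
    inactive (f = 0).  With the assay's 10 mM donor / 6 mM acceptor
    stoichiometry the *observed* fractional conversion ratio of an active
    well is ``10 f / 6`` until the acceptor pool is exhausted (f = 0.6),
    where it saturates at 1.  :meth:`for_observed_ratio` inverts that
    relation for planting targets on the observed scale.
    """

    conversion: dict[tuple[str, str, str], float] = field(default_factory=dict)
    donor_mM: float = 10.0
    acceptor_mM: float = 6.0

    def __post_init__(self):
        for key, f in self.conversion.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"conversion fraction out of [0,1] for {key}: {f}")

    def f(self, enzyme: str, donor: str, acceptor: str) -> float:
        return self.conversion.get((enzyme, donor, acceptor), 0.0)

    def for_observed_ratio(self, ratio: float) -> float:
        """Converted fraction that yields a given observed conversion ratio."""
        if not 0.0 <= ratio <= 1.0:
            raise ValueError("observed ratio must be in [0,1]")
        if ratio >= 1.0:
            return self.acceptor_mM / self.donor_mM
        # ratio = f*d / (f*d + (a - f*d))  =>  f = ratio * a / d  (pre-floor)
        return ratio * self.acceptor_mM / self.donor_mM


@dataclass
class NoiseModel:
    """Multiplicative noise structure of the rendered surface.

    spot_efficiency_cv
        CV of the log-normal desorption/ionization factor shared by every
        ion in a spot (mean 1).
    ion_noise_cv
        CV of independent per-ion Gaussian factors (mean 1, floored at 0).
    baseline_level
        Additive per-pixel intensity present at every panel channel.
    mz_jitter_sd
        SD (Da) of the per-spot peak-position jitter.
    center_jitter_px
        Half-width of the uniform random spot-center offset (pixels).
    """

    spot_efficiency_cv: float = 0.10
    ion_noise_cv: float = 0.03
    baseline_level: float = 2.0
    mz_jitter_sd: float = 0.005
    center_jitter_px: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.spot_efficiency_cv, self.ion_noise_cv, self.mz_jitter_sd) < 0:
            raise ValueError("noise CVs must be non-negative")


def _channel_map(targets: list[AdductTarget]):
    product_by_donor = {t.donor_name: t for t in targets if t.role == "product"}
    acceptor_by_name = {t.source_compound.name: t for t in targets if t.role == "acceptor"}
    return product_by_donor, acceptor_by_name


def ion_amounts(
    design: PlateDesign,
    truth: TruthProfile,
    targets: list[AdductTarget],
    intensity_per_mM: float = 100.0,
) -> pd.DataFrame:
    """Expected (noise-free) ion amounts per well, in intensity counts.

    Product amount is proportional to f x donor concentration; the
    residual acceptor is depleted 1:1 and floored at zero.  Control wells
    carry no product and the full acceptor pool.  Degenerate wells (the
    product channel coincides with the acceptor channel) have both
    amounts summed into the shared channel and are marked not-evaluable.
    """
    product_by_donor, acceptor_by_name = _channel_map(targets)
    rows = []
    for w in design.wells.itertuples(index=False):
        if w.acceptor not in acceptor_by_name:
            raise KeyError(f"acceptor {w.acceptor!r} not in target panel")
        acc_target = acceptor_by_name[w.acceptor]
        if w.donor == CONTROL:
            prod_target = None
            prod_amt = 0.0
            acc_amt = truth.acceptor_mM * intensity_per_mM
            evaluable = True
            note = "control"
        elif w.donor not in product_by_donor:
            # donor without a taggable transamination product (e.g. SAM):
            # the well carries only its acceptor channel and cannot be scored
            prod_target = None
            prod_amt = 0.0
            acc_amt = truth.acceptor_mM * intensity_per_mM
            evaluable = False
            note = "no_product_channel"
        else:
            prod_target = product_by_donor[w.donor]
            f = truth.f(w.enzyme, w.donor, w.acceptor)
            prod_mM = f * truth.donor_mM
            acc_mM = max(0.0, truth.acceptor_mM - prod_mM)
            prod_amt = prod_mM * intensity_per_mM
            acc_amt = acc_mM * intensity_per_mM
            evaluable = True
            note = ""
            if w.acceptor in degenerate_acceptors(prod_target):
                # product indistinguishable from acceptor: one shared channel
                acc_amt = acc_amt + prod_amt
                prod_amt = 0.0
                prod_target = None
                evaluable = False
                note = "degenerate_pair"
        rows.append(
            {
                "well_id": w.well_id,
                "enzyme": w.enzyme,
                "donor": w.donor,
                "acceptor": w.acceptor,
                "replicate": w.replicate,
                "product_channel": prod_target.name if prod_target else "",
                "acceptor_channel": acc_target.name,
                "product_amount": prod_amt,
                "acceptor_amount": acc_amt,
                "evaluable": evaluable,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def gaussian_footprint(center_row: float, center_col: float,
                       rows: np.ndarray, cols: np.ndarray,
                       sigma: float = SPOT_SIGMA_PX) -> np.ndarray:
    """Unnormalized Gaussian spot profile evaluated at pixel centers."""
    d2 = (rows - center_row) ** 2 + (cols - center_col) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _spot_factors(rng: np.random.Generator, noise: NoiseModel, n_wells: int):
    if noise.spot_efficiency_cv > 0:
        sigma_ln = math.sqrt(math.log(1.0 + noise.spot_efficiency_cv**2))
        eff = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=n_wells)
    else:
        eff = np.ones(n_wells)
    return eff


def render(
    design: PlateDesign,
    amounts: pd.DataFrame,
    noise: NoiseModel,
    targets: list[AdductTarget] | None = None,
) -> tuple[MSIDataset, pd.DataFrame]:
    """Rasterize the plate into a centroided MSI dataset plus ground truth.

    Each spot is a 2D Gaussian footprint (FWHM 3 px) at its expected grid
    position plus a uniform random offset of at most
    ``noise.center_jitter_px``.  All ions in a spot share one efficiency
    factor; each ion additionally gets an independent multiplicative
    factor and a per-spot m/z jitter.  A baseline is added at every panel
    channel in every pixel.  Fully reproducible from ``noise.seed``.

    Returns the dataset and a per-well truth table (true centers,
    efficiency factors, rendered amounts, expected ratio).
    """
    rng = np.random.default_rng(noise.seed)
    wells = design.wells.reset_index(drop=True)
    n_wells = len(wells)
    n_rows, n_cols = design.shape

    eff = _spot_factors(rng, noise, n_wells)
    offsets = (
        rng.uniform(-noise.center_jitter_px, noise.center_jitter_px, size=(n_wells, 2))
        if noise.center_jitter_px > 0
        else np.zeros((n_wells, 2))
    )

    channel_mz: dict[str, float] = {}
    if targets is not None:
        channel_mz = {t.name: t.conjugate_mz for t in targets}
    else:
        raise ValueError("render requires the target panel for channel m/z values")

    px_parts, mz_parts, int_parts = [], [], []
    truth_rows = []
    hw = RENDER_HALFWIDTH_PX
    amounts = amounts.set_index("well_id")

    for i, w in enumerate(wells.itertuples(index=False)):
        amt = amounts.loc[w.well_id]
        cr = w.exp_row + offsets[i, 0]
        cc = w.exp_col + offsets[i, 1]
        r0, r1 = int(round(cr)) - hw, int(round(cr)) + hw + 1
        c0, c1 = int(round(cc)) - hw, int(round(cc)) + hw + 1
        rr, cols_ = np.meshgrid(
            np.arange(max(r0, 0), min(r1, n_rows)),
            np.arange(max(c0, 0), min(c1, n_cols)),
            indexing="ij",
        )
        foot = gaussian_footprint(cr, cc, rr, cols_)
        px = (rr * n_cols + cols_).ravel()
        foot_flat = foot.ravel()

        channels = []
        if amt["product_channel"] and amt["product_amount"] > 0:
            channels.append((amt["product_channel"], float(amt["product_amount"])))
        if amt["acceptor_amount"] > 0:
            channels.append((amt["acceptor_channel"], float(amt["acceptor_amount"])))
        for name, amount in channels:
            ion_fac = max(0.0, rng.normal(1.0, noise.ion_noise_cv)) if noise.ion_noise_cv > 0 else 1.0
            mz = channel_mz[name] + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd > 0 else 0.0)
            intensities = amount * eff[i] * ion_fac * foot_flat
            px_parts.append(px)
            mz_parts.append(np.full(px.size, mz))
            int_parts.append(intensities)

        truth_rows.append(
            {
                "well_id": w.well_id,
                "enzyme": w.enzyme,
                "donor": w.donor,
                "acceptor": w.acceptor,
                "replicate": w.replicate,
                "true_row": cr,
                "true_col": cc,
                "efficiency": eff[i],
                "product_amount": float(amt["product_amount"]),
                "acceptor_amount": float(amt["acceptor_amount"]),
                "footprint_sum": float(foot_flat.sum()),
                "evaluable": bool(amt["evaluable"]),
                "true_ratio": (
                    float(amt["product_amount"]) / (float(amt["product_amount"]) + float(amt["acceptor_amount"]))
                    if (amt["product_amount"] + amt["acceptor_amount"]) > 0
                    else np.nan
                ),
            }
        )

    # uniform baseline at every panel channel in every pixel
    if noise.baseline_level > 0 and channel_mz:
        all_px = np.arange(n_rows * n_cols, dtype=np.int64)
        for mz in channel_mz.values():
            if noise.ion_noise_cv > 0:
                fac = np.clip(rng.normal(1.0, noise.ion_noise_cv, size=all_px.size), 0.0, None)
            else:
                fac = 1.0
            px_parts.append(all_px)
            mz_parts.append(np.full(all_px.size, mz))
            int_parts.append(noise.baseline_level * fac * np.ones(all_px.size))

    dataset = MSIDataset(
        shape=design.shape,
        pixel_px=np.concatenate(px_parts) if px_parts else np.empty(0, np.int64),
        peak_mz=np.concatenate(mz_parts) if mz_parts else np.empty(0),
        peak_intensity=np.concatenate(int_parts) if int_parts else np.empty(0),
        pixel_size_um=design.pixel_size_um,
    )
    return dataset, pd.DataFrame(truth_rows)


def simulate_intensities(
    design: PlateDesign,
    amounts: pd.DataFrame,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Spot-statistics shortcut: per-well extracted intensities, no imaging.

    Draws the same noise structure as :func:`render` (shared spot
    efficiency, independent ion factors, baseline) but reports the
    spot-mean intensities directly.  Useful for large replicate studies
    of the scoring rule where rasterization adds nothing.
    """
    rng = np.random.default_rng(noise.seed)
    n = len(amounts)
    eff = _spot_factors(rng, noise, n)
    out = amounts.copy()
    prod, acc = [], []
    for i, row in enumerate(amounts.itertuples(index=False)):
        ion_p = max(0.0, rng.normal(1.0, noise.ion_noise_cv)) if noise.ion_noise_cv > 0 else 1.0
        ion_a = max(0.0, rng.normal(1.0, noise.ion_noise_cv)) if noise.ion_noise_cv > 0 else 1.0
        prod.append(noise.baseline_level + row.product_amount * eff[i] * ion_p)
        acc.append(noise.baseline_level + row.acceptor_amount * eff[i] * ion_a)
    out["I_product"] = prod
    out["I_acceptor"] = acc
    return out
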