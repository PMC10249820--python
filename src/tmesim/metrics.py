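"""Derived outputs: cell counts, metabolic ratios, drug delivery, clusters,
invasion geometry and tumor IFP.

The *tumor region* for spatial averages is the morphological closure of the
viable + necrotic cell mask (the tumor boundary is a contour, not a formula);
*normal tissue* is its complement.  The hypoxia / hypoglycemia thresholds are
the characteristic concentrations of the vitality model.  The *drug delivery
factor* is the running time integral of anti-cancer drug concentration
sampled at live (proliferative + quiescent) cell nodes, normalized by the
current live-cell count; drug sitting in necrotic regions is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cells import Phenotype

#: 6-connected structuring element
STRUCTURE = ndimage.generate_binary_structure(3, 1)


def tumor_region_mask(lattice) -> np.ndarray:
    """Morphological closure of the viable + necrotic mask."""
    any_tumor = lattice.live_mask | lattice.necrotic_mask
    if not any_tumor.any():
        return any_tumor
    closed = ndimage.binary_closing(any_tumor, structure=STRUCTURE, iterations=2)
    return ndimage.binary_fill_holes(closed, structure=STRUCTURE)


def hypoxic_ratio(fields, lattice, threshold: float | None = None,
                  params=None) -> float:
    """Fraction of tumor-occupied nodes with oxygen below threshold."""
    return _deficit_ratio(fields["o2"], lattice,
                          threshold if threshold is not None else params.c_o2_ch)


def hypoglycemic_ratio(fields, lattice, threshold: float | None = None,
                       params=None) -> float:
    return _deficit_ratio(fields["g"], lattice,
                          threshold if threshold is not None else params.c_g_ch)


def _deficit_ratio(conc, lattice, threshold) -> float:
    occupied = lattice.live_mask | lattice.necrotic_mask
    n = int(occupied.sum())
    if n == 0:
        raise ValueError("empty tumor")
    return float((conc[occupied] < threshold).sum()) / n


@dataclass
class DrugDeliveryAccumulator:
    """Running integral of drug concentration over live cancer cells."""

    integral: float = 0.0   # sum over live cells of c_ac, integrated in time

    def accumulate(self, fields, lattice, dt: float) -> None:
        live = lattice.live_mask
        if live.any():
            self.integral += float(fields["ac"][live].sum()) * dt

    def value(self, lattice) -> float | None:
        """Time-integrated drug over live cells per current live cell; None
        (reported as missing) once no live cells remain."""
        n_live = int(lattice.live_mask.sum())
        if n_live == 0:
            return None
        return self.integral / n_live


def drug_delivery_factor(history_integral: float, n_live: int) -> float:
    if n_live < 1:
        raise ValueError("undefined for zero live cells")
    return history_integral / n_live


def find_clusters(lattice, center_mm=None, spacing=None) -> list[dict]:
    """6-connected components of viable cells: size and centroid distance
    from the tumor seeding center (domain center by default)."""
    viable = lattice.live_mask
    labels, n = ndimage.label(viable, structure=STRUCTURE)
    if n == 0:
        return []
    shape = viable.shape
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    if center_mm is None:
        center_mm = tuple((s - 1) / 2.0 * h for s, h in zip(shape, spacing))
    clusters = []
    centroids = ndimage.center_of_mass(viable, labels, range(1, n + 1))
    sizes = ndimage.sum_labels(viable, labels, range(1, n + 1))
    for size, com in zip(sizes, centroids):
        pos = tuple(c * h for c, h in zip(com, spacing))
        dist = float(np.sqrt(sum((p - c) ** 2 for p, c in zip(pos, center_mm))))
        clusters.append({"size": int(size), "distance_mm": dist})
    return clusters


def invasion_metrics(lattice, spacing, center_mm=None) -> dict[str, float]:
    """Farthest viable cell from the tumor center along z and in the x-y
    plane, plus the z/planar aspect ratio of the viable mask."""
    viable = lattice.live_mask
    if not viable.any():
        raise ValueError("no viable cells")
    idx = np.argwhere(viable)
    if center_mm is None:
        center_mm = tuple(
            (s - 1) / 2.0 * h for s, h in zip(viable.shape, spacing)
        )
    pos = idx * np.asarray(spacing)
    dz = np.abs(pos[:, 2] - center_mm[2])
    dplan = np.sqrt((pos[:, 0] - center_mm[0]) ** 2 + (pos[:, 1] - center_mm[1]) ** 2)
    z_extent = float(pos[:, 2].max() - pos[:, 2].min())
    x_extent = float(pos[:, 0].max() - pos[:, 0].min())
    y_extent = float(pos[:, 1].max() - pos[:, 1].min())
    planar_mean = 0.5 * (x_extent + y_extent)
    aspect = z_extent / planar_mean if planar_mean > 0 else 1.0
    return {
        "max_z_distance_mm": float(dz.max()),
        "max_planar_distance_mm": float(dplan.max()),
        "aspect_ratio": float(aspect),
    }


def mean_tumor_ifp(ifp: np.ndarray, lattice) -> float:
    mask = tumor_region_mask(lattice)
    if not mask.any():
        return 0.0
    return float(ifp[mask].mean())


def mean_drug_concentration(fields, lattice, species: str = "ac") -> dict[str, float]:
    """Spatial averages of a drug field over tumor region and normal tissue."""
    mask = tumor_region_mask(lattice)
    c = fields[species]
    tumor = float(c[mask].mean()) if mask.any() else 0.0
    normal = float(c[~mask].mean()) if (~mask).any() else 0.0
    return {"tumor": tumor, "normal": normal}


@dataclass
class MetricsRecorder:
    """Per-step tidy metric rows; exportable as a DataFrame / CSV."""

    params: object
    spacing: tuple
    delivery: DrugDeliveryAccumulator = field(default_factory=DrugDeliveryAccumulator)
    rows: list[dict] = field(default_factory=list)

    def record(self, t_days: float, fields, lattice, flow_state=None) -> dict:
        counts = lattice.counts()
        row = {"time_days": t_days, **counts}
        if counts["total"] > 0:
            p = self.params
            row["hypoxic_ratio"] = hypoxic_ratio(
                fields, lattice, threshold=p.hypoxia_threshold * p.c_o2_ch
            )
            row["hypoglycemic_ratio"] = hypoglycemic_ratio(
                fields, lattice, threshold=p.hypoglycemia_threshold * p.c_g_ch
            )
        else:
            row["hypoxic_ratio"] = np.nan
            row["hypoglycemic_ratio"] = np.nan
        drug = mean_drug_concentration(fields, lattice)
        row["mean_tumor_drug"] = drug["tumor"]
        row["mean_normal_drug"] = drug["normal"]
        ddf = self.delivery.value(lattice)
        row["drug_delivery_factor"] = np.nan if ddf is None else ddf
        if flow_state is not None and flow_state.ifp is not None:
            row["mean_tumor_ifp"] = mean_tumor_ifp(flow_state.ifp, lattice)
        else:
            row["mean_tumor_ifp"] = np.nan
        if lattice.live_mask.any():
            row.update(invasion_metrics(lattice, self.spacing))
        self.rows.append(row)
        return row

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)
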