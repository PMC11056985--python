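"""Free-energy surfaces over (HB count, end-to-end distance).

Bins the joint occupancy of the total hydrogen-bond count and the
end-to-end distance, converts occupancy to free energy G = -RT ln(Omega),
and extracts the per-level distance centers of mass x_i whose squared
increments feed the global friction coefficient.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_KJ_PER_MOL_K",
    "FreeEnergySurface",
    "DeltaXResult",
    "build_surface",
    "histogram_centers",
    "write_surface",
    "plot_surface",
]

#: Ideal gas constant in kJ/(mol K).
R_KJ_PER_MOL_K = 8.314462618e-3


@dataclass
class FreeEnergySurface:
    """Binned (HB level x distance) occupancy with free energies.

    ``free_energy`` is NaN wherever a bin is empty (-RT ln 0 is undefined,
    never coerced to 0).  The raw series are retained so that per-level
    centers of mass can be computed from samples rather than bin midpoints.
    """

    hb_levels: np.ndarray
    distance_edges: np.ndarray
    counts: np.ndarray  # (n_levels, n_bins)
    free_energy: np.ndarray  # kJ/mol, NaN where counts == 0
    temperature: float
    h_series: np.ndarray = field(repr=False)
    e2e_series: np.ndarray = field(repr=False)

    @property
    def level_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class DeltaXResult:
    """Per-level histogram centers of mass and their increments.

    ``delta_x_reported = sqrt(sum_i delta_x_i^2)`` is the scalar the global
    friction uses.
    """

    levels: np.ndarray
    x_centers: np.ndarray  # nm
    delta_x_steps: np.ndarray  # nm
    delta_x_sq_total: float  # nm^2
    delta_x_reported: float  # nm
    excluded_levels: list


def build_surface(
    h_series: np.ndarray,
    e2e_series: np.ndarray,
    bin_width: float = 0.05,
    temperature: float = 300.0,
    h_max: int | None = None,
    shift_min: bool = True,
) -> FreeEnergySurface:
    """Build the 2-D occupancy and free-energy surface.

    G = -RT ln(Omega) per occupied bin (kJ/mol); when ``shift_min`` the
    minimum over occupied bins is shifted to zero.
    """
    h = np.asarray(h_series, dtype=int)
    x = np.asarray(e2e_series, dtype=float)
    if h.size == 0 or x.size == 0:
        raise ValueError("empty series")
    if h.size != x.size:
        raise ValueError("h_series and e2e_series must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if h_max is None:
        h_max = int(h.max())
    levels = np.arange(h_max + 1)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((levels.size, n_bins), dtype=np.int64)
    for lv in levels:
        sel = h == lv
        if sel.any():
            counts[lv], _ = np.histogram(x[sel], bins=edges)
    with np.errstate(divide="ignore"):
        g = np.where(
            counts > 0,
            -R_KJ_PER_MOL_K * temperature * np.log(np.maximum(counts, 1e-300)),
            np.nan,
        )
    if shift_min and np.isfinite(g).any():
        g = g - np.nanmin(g)
    return FreeEnergySurface(
        hb_levels=levels,
        distance_edges=edges,
        counts=counts,
        free_energy=g,
        temperature=temperature,
        h_series=h,
        e2e_series=x,
    )


def histogram_centers(surface: FreeEnergySurface, min_count: int = 50) -> DeltaXResult:
    """Per-level centers of mass x_i and their squared-increment total.

    x_i is the count-weighted mean end-to-end distance of frames at HB
    level i, computed from the raw samples (binning is for display only,
    which removes any bin-width dependence).  Levels with fewer than
    ``min_count`` frames are excluded and reported; increments run between
    consecutive surviving levels.
    """
    h, x = surface.h_series, surface.e2e_series
    levels, centers, excluded = [], [], []
    for lv in surface.hb_levels:
        sel = h == lv
        n = int(sel.sum())
        if n >= min_count:
            levels.append(int(lv))
            centers.append(float(x[sel].mean()))
        else:
            excluded.append((int(lv), n))
    if len(levels) < 2:
        raise ValueError("no folding path: fewer than 2 usable HB levels")
    centers = np.asarray(centers)
    steps = np.diff(centers)
    total = float((steps**2).sum())
    return DeltaXResult(
        levels=np.asarray(levels),
        x_centers=centers,
        delta_x_steps=steps,
        delta_x_sq_total=total,
        delta_x_reported=float(np.sqrt(total)),
        excluded_levels=excluded,
    )


def write_surface(path, surface: FreeEnergySurface) -> None:
    """Write Omega and G matrices as delimited text with level and
    bin-edge headers."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K = {surface.temperature}\n")
        fh.write("# distance_bin_edges_nm = "
                 + " ".join(f"{e:.6g}" for e in surface.distance_edges) + "\n")
        fh.write("# matrix = counts; rows are HB levels 0..h_max\n")
        for lv, row in zip(surface.hb_levels, surface.counts):
            fh.write(f"{lv}\t" + "\t".join(str(int(c)) for c in row) + "\n")
        fh.write("# matrix = free_energy_kJ_mol; empty bins written as nan\n")
        for lv, row in zip(surface.hb_levels, surface.free_energy):
            fh.write(f"{lv}\t" + "\t".join(f"{g:.6g}" for g in row) + "\n")


def plot_surface(path, surface: FreeEnergySurface) -> None:
    """Render the free-energy surface to a heat-map image (requires
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    extent = (
        surface.distance_edges[0],
        surface.distance_edges[-1],
        surface.hb_levels[0] - 0.5,
        surface.hb_levels[-1] + 0.5,
    )
    im = ax.imshow(
        surface.free_energy,
        origin="lower",
        aspect="auto",
        extent=extent,
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="G [kJ/mol]")
    ax.set_xlabel("end-to-end distance [nm]")
    ax.set_ylabel("number of HBs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
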