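"""Conformational landscape of the AcuB dimer.

Two scalar order parameters summarise the dimer's motions per frame:

* **opening** - the centre-of-mass distance between the N-terminal CBS
  modules (residues 1-82) of the two monomers, reporting the transverse
  opening of the scissor-shaped dimer;
* **jacking** - the centre-of-mass distance of the ACT domain (residues
  135-214) from the Bateman-domain region (residues 1-134) of a monomer,
  reporting longitudinal extension of the "handle".

The joint distribution over (opening, jacking) is binned, normalised and
Boltzmann-inverted into a free-energy surface

    dG = -R T ln(P / max(P)),

so the modal bin sits at dG = 0 and empty bins are undefined (masked,
never an infinity used in arithmetic).  Conformational basins are found
with density-based OPTICS clustering of the per-frame order-parameter
points (axes standardised to unit variance first) and categorised as
closed/compact, open/compact or extended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import OPTICS, cluster_optics_dbscan

from .geometry import center_of_mass, masses_for
from .structio import Selection, Structure, Trajectory, select_atoms

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "OrderParameterSeries",
    "FreeEnergySurface",
    "BasinResult",
    "compute_order_parameters",
    "boltzmann_invert",
    "free_energy_surface",
    "optics_cluster",
    "categorize_and_populate",
]

#: gas constant in kcal/(mol K)
GAS_CONSTANT_KCAL = 1.987204e-3
#: simulation base temperature (K)
DEFAULT_TEMPERATURE = 310.0


@dataclass
class OrderParameterSeries:
    """Per-frame (opening, jacking) values in A, plus optional truth labels."""

    opening: np.ndarray
    jacking: np.ndarray
    jacking_per_monomer: np.ndarray | None = None
    frame_ids: np.ndarray | None = None
    state_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.opening = np.asarray(self.opening, dtype=float)
        self.jacking = np.asarray(self.jacking, dtype=float)
        if self.opening.shape != self.jacking.shape:
            raise ValueError("opening and jacking must have equal length")
        if not (np.all(np.isfinite(self.opening)) and np.all(np.isfinite(self.jacking))):
            raise ValueError("order parameters must be finite")
        if np.any(self.opening <= 0) or np.any(self.jacking <= 0):
            raise ValueError("order parameters must be positive distances")
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(self.opening))

    def __len__(self) -> int:
        return len(self.opening)

    def points(self) -> np.ndarray:
        return np.column_stack([self.opening, self.jacking])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"frame": self.frame_ids, "opening_A": self.opening, "jacking_A": self.jacking}
        )
        if self.state_labels is not None:
            df["state"] = self.state_labels
        return df


def compute_order_parameters(
    traj: Trajectory,
    monomer_chains: tuple[str, str] = ("A", "B"),
    aggregation: str = "max",
    cbs_range: tuple[int, int] = (1, 82),
    act_range: tuple[int, int] = (135, 214),
    bateman_range: tuple[int, int] = (1, 134),
    mass_mode: str = "atomic",
) -> OrderParameterSeries:
    """Compute per-frame opening and jacking distances for a dimer.

    ``aggregation`` controls how the two per-monomer jacking distances are
    merged: ``"max"`` (default - sensitive to detachment of either ACT
    domain), ``"mean"``, or ``"per-monomer"`` (keeps both; the ``jacking``
    field then holds the max while ``jacking_per_monomer`` carries the
    full (n_frames, 2) array).
    """
    cha, chb = monomer_chains
    top = traj.topology

    def _idx(chain: str, rng: tuple[int, int]) -> np.ndarray:
        idx = select_atoms(top, Selection(chains={chain}, residue_range=rng))
        if len(idx) == 0:
            raise ValueError(f"selection chain {chain} residues {rng} is empty")
        return idx

    groups = {
        "open_a": _idx(cha, cbs_range),
        "open_b": _idx(chb, cbs_range),
        "act_a": _idx(cha, act_range),
        "act_b": _idx(chb, act_range),
        "bat_a": _idx(cha, bateman_range),
        "bat_b": _idx(chb, bateman_range),
    }
    # vectorised mass-weighted COM per group over all frames
    coms = {}
    for key, idx in groups.items():
        m = masses_for(top, idx, mass_mode)
        coms[key] = np.einsum("fij,i->fj", traj.frames[:, idx, :], m) / m.sum()
    opening = np.linalg.norm(coms["open_a"] - coms["open_b"], axis=1)
    jack = np.column_stack(
        [
            np.linalg.norm(coms["act_a"] - coms["bat_a"], axis=1),
            np.linalg.norm(coms["act_b"] - coms["bat_b"], axis=1),
        ]
    )
    if aggregation == "max":
        jagg = jack.max(axis=1)
        per = None
    elif aggregation == "mean":
        jagg = jack.mean(axis=1)
        per = None
    elif aggregation == "per-monomer":
        jagg = jack.max(axis=1)
        per = jack
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return OrderParameterSeries(opening, jagg, jacking_per_monomer=per)


@dataclass
class FreeEnergySurface:
    """Binned probability grid and Boltzmann-inverted dG (kcal/mol).

    ``delta_g`` is a masked array: empty bins are masked (undefined).  The
    minimum over defined bins is exactly 0 at the modal bin.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    delta_g: np.ma.MaskedArray
    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "x_center": xx.ravel(),
                "y_center": yy.ravel(),
                "probability": self.probability.ravel(),
                "delta_g_kcal_mol": self.delta_g.filled(np.nan).ravel(),
            }
        )


def boltzmann_invert(
    probability: np.ndarray,
    gas_constant: float = GAS_CONSTANT_KCAL,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ma.MaskedArray:
    """dG = -RT ln(P / max(P)) with empty (P = 0) bins masked as undefined.

    Depends only on the ratio P / max(P), so any common positive rescaling
    of P leaves the surface unchanged; the modal bin is exactly 0.
    """
    prob = np.asarray(probability, dtype=float)
    if np.any(prob < 0) or not np.all(np.isfinite(prob)):
        raise ValueError("probabilities must be finite and non-negative")
    pmax = prob.max()
    if pmax <= 0:
        raise ValueError("probability grid is identically zero")
    empty = prob <= 0
    with np.errstate(divide="ignore"):
        dg = -gas_constant * temperature * np.log(np.where(empty, 1.0, prob) / pmax)
    dg = dg + 0.0  # normalise -0.0 at the modal bin
    return np.ma.MaskedArray(dg, mask=empty)


def free_energy_surface(
    x: np.ndarray,
    y: np.ndarray,
    bins: int | tuple[int, int] = 60,
    gas_constant: float = GAS_CONSTANT_KCAL,
    temperature: float = DEFAULT_TEMPERATURE,
    range_pad: float = 0.02,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> FreeEnergySurface:
    """2D histogram of (x, y) converted to a free-energy surface.

    The histogram is normalised to total probability mass 1 and inverted
    with dG = -RT ln(P / max(P)).  Bin ranges default to [min, max] of
    each axis padded by ``range_pad`` (2%) on both sides; explicit
    ``edges`` override this.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1D series")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input series")
    if edges is None:
        nx, ny = (bins, bins) if np.isscalar(bins) else bins

        def _edges(v: np.ndarray, n: int) -> np.ndarray:
            lo, hi = float(v.min()), float(v.max())
            span = (hi - lo) or 1.0
            return np.linspace(lo - range_pad * span, hi + range_pad * span, n + 1)

        edges = (_edges(x, int(nx)), _edges(y, int(ny)))
    counts, xe, ye = np.histogram2d(x, y, bins=edges)
    prob = counts / counts.sum()
    delta_g = boltzmann_invert(prob, gas_constant, temperature)
    return FreeEnergySurface(xe, ye, prob, delta_g, gas_constant, temperature)


@dataclass
class BasinResult:
    """OPTICS clustering outcome on order-parameter points.

    ``labels`` is per-point (-1 = noise); ``reachability``/``ordering``
    expose the OPTICS reachability profile; ``table`` lists one row per
    basin with count, population fraction and centroid (in A).
    """

    labels: np.ndarray
    reachability: np.ndarray
    ordering: np.ndarray
    table: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return int(len(self.table))


def optics_cluster(
    points: np.ndarray,
    min_samples: int = 50,
    extraction: str = "xi",
    xi: float = 0.05,
    eps: float | None = None,
    max_eps: float = np.inf,
    standardize: bool = True,
) -> BasinResult:
    """Cluster 2D order-parameter points into conformational basins.

    Runs scikit-learn OPTICS to obtain the density ordering and
    reachability profile, then extracts clusters either with the xi
    steepness method (``extraction="xi"``) or with a flat eps cut
    (``extraction="eps-cut"``; equivalent to DBSCAN core-point labelling
    at the same eps/min_samples).  Axes are standardised to unit variance
    before clustering so that opening and jacking contribute equally;
    ``eps``/``max_eps`` are then in standardised units.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < min_samples:
        raise ValueError(
            f"need at least min_samples={min_samples} points, got {pts.shape[0]}"
        )
    if standardize:
        scale = pts.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        work = (pts - pts.mean(axis=0)) / scale
    else:
        work = pts
    if extraction == "xi":
        model = OPTICS(min_samples=min_samples, xi=xi, max_eps=max_eps,
                       cluster_method="xi")
        model.fit(work)
        labels = model.labels_
    elif extraction == "eps-cut":
        if eps is None:
            raise ValueError("eps-cut extraction requires eps")
        model = OPTICS(min_samples=min_samples, max_eps=max(eps * 1.5, eps + 1e-9),
                       cluster_method="dbscan", eps=eps)
        model.fit(work)
        labels = cluster_optics_dbscan(
            reachability=model.reachability_,
            core_distances=model.core_distances_,
            ordering=model.ordering_,
            eps=eps,
        )
    else:
        raise ValueError(f"unknown extraction {extraction!r}")
    n = pts.shape[0]
    rows = []
    for lab in sorted(set(labels) - {-1}):
        mask = labels == lab
        rows.append(
            {
                "label": int(lab),
                "count": int(mask.sum()),
                "population": float(mask.sum() / n),
                "centroid_opening_A": float(pts[mask, 0].mean()),
                "centroid_jacking_A": float(pts[mask, 1].mean()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["label", "count", "population", "centroid_opening_A", "centroid_jacking_A"],
    )
    return BasinResult(
        labels=np.asarray(labels),
        reachability=model.reachability_[model.ordering_],
        ordering=model.ordering_,
        table=table,
    )


CATEGORIES = ("closed/compact", "open/compact", "extended")


def categorize_and_populate(
    basins: BasinResult,
    opening_threshold: float | None = None,
    jacking_threshold: float | None = None,
) -> pd.DataFrame:
    """Tag each basin as closed/compact, open/compact or extended.

    A basin is *extended* when its jacking centroid exceeds the jacking
    threshold; otherwise the opening centroid splits *closed/compact*
    (below) from *open/compact* (above).  Thresholds default to the
    median of the basin centroids on each axis (data-driven split);
    absolute thresholds in A can be supplied instead.  Centroids exactly
    on a threshold fall in the lower category.
    """
    table = basins.table.copy()
    if table.empty:
        table["category"] = pd.Series(dtype=str)
        return table
    if jacking_threshold is None:
        jacking_threshold = float(table["centroid_jacking_A"].median())
    if opening_threshold is None:
        opening_threshold = float(table["centroid_opening_A"].median())
    cats = []
    for _, row in table.iterrows():
        if row["centroid_jacking_A"] > jacking_threshold:
            cats.append("extended")
        elif row["centroid_opening_A"] > opening_threshold:
            cats.append("open/compact")
        else:
            cats.append("closed/compact")
    table["category"] = cats
    return table
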