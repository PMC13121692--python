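"""Synthetic inputs with exact ground truth for every pipeline stage.

Real replica-exchange ensembles and bench measurements are expensive and
not redistributable, so each analysis stage is exercised against
generated data whose true answer is known:

* :func:`gen_dimer_trajectory` builds a pseudo-atom AcuB dimer (two
  214-residue chains, one atom per residue) whose per-frame (opening,
  jacking) order parameters follow a discrete-state Markov mixture with
  AR(1) within-state correlation; domain blocks are rigidly translated so
  the realised centre-of-mass distances equal the sampled targets to
  machine precision.
* :func:`gen_complex_trajectory` emulates bound-complex runs: the AcuB
  chains stay internally rigid while the AcuC chains wobble with a
  condition-dependent AR(1) displacement; the exact per-frame
  displacement magnitude (= the alignment-corrected RMSD) is recorded.
* :func:`gen_assay_data` produces dose-response, melt, mixture,
  absorbance, chromatogram and SEC tables from the corresponding forward
  models.

Identical (spec, seed) pairs give identical output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import dose_response_model
from .structio import Atom, Structure, Trajectory

__all__ = [
    "DEFAULT_SEED",
    "StateSpec",
    "DimerSpec",
    "GroundTruth",
    "gen_dimer_trajectory",
    "ComplexCondition",
    "DEFAULT_COMPLEX_CONDITIONS",
    "gen_complex_trajectory",
    "gen_assay_data",
]

DEFAULT_SEED = 20260424


@dataclass(frozen=True)
class StateSpec:
    """One conformational state: mean (opening, jacking) in A + 2x2 covariance."""

    opening_mean: float
    jacking_mean: float
    cov: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    name: str = ""


#: default three-state mixture: a dominant closed/compact basin, a
#: partially opened basin and a longitudinally extended basin, separated
#: by >= 8 A on the relevant axis.
DEFAULT_STATES = (
    StateSpec(20.0, 14.0, name="closed/compact"),
    StateSpec(32.0, 14.0, name="open/compact"),
    StateSpec(22.0, 26.0, name="extended"),
)
DEFAULT_POPULATIONS = (0.6, 0.3, 0.1)


def _default_transition_matrix(populations: np.ndarray, mixing: float) -> np.ndarray:
    """Row-stochastic matrix (1-mixing)*I + mixing*1 pi^T.

    Its stationary distribution is exactly ``populations`` for any
    ``mixing`` in (0, 1]; smaller mixing gives longer state dwell times.
    """
    n = len(populations)
    return (1.0 - mixing) * np.eye(n) + mixing * np.tile(populations, (n, 1))


@dataclass
class DimerSpec:
    """Generator settings for a synthetic AcuB-dimer ensemble."""

    n_frames: int = 20000
    states: tuple[StateSpec, ...] = DEFAULT_STATES
    populations: tuple[float, ...] = DEFAULT_POPULATIONS
    transition_matrix: np.ndarray | None = None
    mixing: float = 0.4
    phi: float = 0.8
    residues_per_monomer: int = 214
    seed: int = DEFAULT_SEED

    def resolved_transition_matrix(self) -> np.ndarray:
        pops = np.asarray(self.populations, dtype=float)
        if abs(pops.sum() - 1.0) > 1e-9 or np.any(pops < 0):
            raise ValueError("populations must be non-negative and sum to 1")
        if len(pops) != len(self.states):
            raise ValueError("populations and states must have equal length")
        if self.transition_matrix is None:
            tm = _default_transition_matrix(pops, self.mixing)
        else:
            tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (len(pops), len(pops)) or np.any(tm < 0):
            raise ValueError("transition matrix must be square and non-negative")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        stat = _stationary_distribution(tm)
        if not np.allclose(stat, pops, atol=1e-9):
            raise ValueError(
                "transition matrix stationary distribution "
                f"{stat} differs from stated populations {pops}"
            )
        return tm


def _stationary_distribution(tm: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(tm.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    return v / v.sum()


@dataclass
class GroundTruth:
    """What the generator actually planted, frame by frame."""

    state_labels: np.ndarray | None = None
    opening: np.ndarray | None = None
    jacking: np.ndarray | None = None
    populations: np.ndarray | None = None
    transition_matrix: np.ndarray | None = None
    displacement: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _blob(rng: np.random.Generator, n: int, spread: float) -> np.ndarray:
    """A reproducible rigid cloud of n pseudo-atoms centred at the origin."""
    pts = rng.normal(scale=spread, size=(n, 3))
    return pts - pts.mean(axis=0)


def _pseudo_topology(chains: dict[str, int], rng: np.random.Generator,
                     spread: float = 4.0) -> Structure:
    atoms = []
    coords = []
    for chain, n_res in chains.items():
        cloud = _blob(rng, n_res, spread)
        for i in range(n_res):
            atoms.append(
                Atom(chain=chain, resnum=i + 1, resname="GLY", name="CA", element="C")
            )
            coords.append(cloud[i])
    return Structure(atoms, np.array(coords))


def _chol_psd(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor that also accepts singular (e.g. zero) covariances."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if np.any(w < -1e-12):
            raise ValueError("state covariance must be positive semi-definite")
        return v * np.sqrt(np.clip(w, 0.0, None))


def _markov_states(rng: np.random.Generator, tm: np.ndarray, pops: np.ndarray,
                   n: int) -> np.ndarray:
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(len(pops), p=pops)
    for t in range(1, n):
        states[t] = rng.choice(len(pops), p=tm[states[t - 1]])
    return states


def gen_dimer_trajectory(spec: DimerSpec | None = None) -> tuple[Trajectory, GroundTruth]:
    """Generate a dimer trajectory with planted order parameters.

    Two 214-residue pseudo-monomers (chains A and B, one atom per
    residue) are built from fixed rigid blocks: the Bateman block
    (residues 1-134, containing the CBS modules 1-82) and the ACT block
    (residues 135-214).  Per frame a Markov state is drawn, a target
    (opening, jacking) pair is sampled from the state's Gaussian with
    AR(1) temporal smoothing, and the blocks are rigidly translated so
    the realised COM distances equal those targets exactly: the opening
    along x (between the residue 1-82 COMs of the monomers) and the
    jacking along y (ACT COM vs Bateman COM, identically for both
    monomers, so any aggregation rule recovers the planted value).
    """
    spec = spec or DimerSpec()
    tm = spec.resolved_transition_matrix()
    pops = np.asarray(spec.populations, dtype=float)
    rng = np.random.default_rng(spec.seed)
    n_res = spec.residues_per_monomer
    top = _pseudo_topology({"A": n_res, "B": n_res}, rng)

    states = _markov_states(rng, tm, pops, spec.n_frames)
    # standardised 2D AR(1) innovations, scaled per-state by Cholesky factors
    chol = [_chol_psd(np.asarray(s.cov, dtype=float)) for s in spec.states]
    e = np.empty((spec.n_frames, 2))
    e[0] = rng.standard_normal(2)
    innov = rng.standard_normal((spec.n_frames, 2))
    sq = np.sqrt(1.0 - spec.phi**2)
    for t in range(1, spec.n_frames):
        e[t] = spec.phi * e[t - 1] + sq * innov[t]
    means = np.array([[s.opening_mean, s.jacking_mean] for s in spec.states])
    # state-specific scaling of the shared standardised AR(1) process
    scaled = np.einsum("tij,tj->ti", np.array(chol)[states], e)
    targets = means[states] + scaled
    # keep distances physical
    targets = np.clip(targets, 1.0, None)

    bat_a = top.coords[:n_res][:134]
    act_a = top.coords[:n_res][134:]
    bat_b = top.coords[n_res:][:134]
    act_b = top.coords[n_res:][134:]
    cbs_a_off = bat_a[:82].mean(axis=0)        # COM of residues 1-82 within block
    cbs_b_off = bat_b[:82].mean(axis=0)
    xhat = np.array([1.0, 0.0, 0.0])
    yhat = np.array([0.0, 1.0, 0.0])

    frames = np.empty((spec.n_frames, top.n_atoms, 3))
    for t in range(spec.n_frames):
        o, j = targets[t]
        a_bat = bat_a                                     # A Bateman at origin
        b_bat = bat_b - cbs_b_off + cbs_a_off + o * xhat  # planted opening
        a_act = act_a - act_a.mean(axis=0) + a_bat.mean(axis=0) + j * yhat
        b_act = act_b - act_b.mean(axis=0) + b_bat.mean(axis=0) + j * yhat
        frames[t, :134] = a_bat
        frames[t, 134:n_res] = a_act
        frames[t, n_res : n_res + 134] = b_bat
        frames[t, n_res + 134 :] = b_act

    truth = GroundTruth(
        state_labels=states,
        opening=targets[:, 0].copy(),
        jacking=targets[:, 1].copy(),
        populations=pops,
        transition_matrix=tm,
        params={"state_names": [s.name for s in spec.states], "phi": spec.phi},
    )
    return Trajectory(top, frames), truth


@dataclass(frozen=True)
class ComplexCondition:
    """Positional wobble of bound AcuC under one nucleotide-loading state.

    ``sigma`` is the stationary standard deviation (A) of the AR(1)
    displacement of the AcuC chains relative to rigid AcuB; larger sigma
    emulates weaker binding or increased flexibility.  ``drift`` adds a
    deterministic linear displacement (A/frame) for convergence testing.
    """

    sigma: float
    drift: float = 0.0
    phi: float = 0.9

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


#: nucleotide-loading conditions emulated by default: nucleotide-free
#: AcuB binds AcuC loosely (large wobble), AMP-loaded AcuB most tightly.
DEFAULT_COMPLEX_CONDITIONS: dict[str, ComplexCondition] = {
    "apo": ComplexCondition(sigma=3.0),
    "AMP": ComplexCondition(sigma=0.75),
    "AMP/ADP": ComplexCondition(sigma=1.0),
    "ATP": ComplexCondition(sigma=1.5),
}


def gen_complex_trajectory(
    conditions: dict[str, ComplexCondition] | None = None,
    n_frames: int = 4000,
    seed: int = DEFAULT_SEED,
    n_res_acub: int = 120,
    n_res_acuc: int = 80,
) -> dict[str, tuple[Trajectory, GroundTruth]]:
    """Generate bound-complex trajectories per nucleotide condition.

    The AcuB chains (A, B) are held internally rigid; the AcuC chains
    (C, D) are displaced together along a fixed axis by an AR(1) series
    d(t) of stationary sd ``sigma`` (plus optional drift).  Every frame
    additionally receives a random global rigid rotation + translation,
    which reference alignment must remove; the planted |d(t)| is then
    exactly the aligned RMSD of the AcuC chains.
    """
    conditions = conditions if conditions is not None else DEFAULT_COMPLEX_CONDITIONS
    out: dict[str, tuple[Trajectory, GroundTruth]] = {}
    for k, (name, cond) in enumerate(sorted(conditions.items())):
        rng = np.random.default_rng([seed, k])
        top = _pseudo_topology(
            {"A": n_res_acub, "B": n_res_acub, "C": n_res_acuc, "D": n_res_acuc},
            rng,
            spread=6.0,
        )
        n_b = 2 * n_res_acub
        d = np.empty(n_frames)
        d[0] = 0.0
        sq = np.sqrt(max(1.0 - cond.phi**2, 0.0))
        innov = rng.standard_normal(n_frames)
        for t in range(1, n_frames):
            d[t] = cond.phi * d[t - 1] + sq * cond.sigma * innov[t]
        d = d + cond.drift * np.arange(n_frames)
        axis = np.array([1.0, 0.0, 0.0])
        frames = np.tile(top.coords, (n_frames, 1, 1))
        frames[:, n_b:, :] += d[:, None, None] * axis
        # random global rigid motion per frame (frame 0 left in place so it
        # is the natural reference)
        for t in range(1, n_frames):
            rot = _random_rotation(rng)
            shift = rng.normal(scale=5.0, size=3)
            frames[t] = frames[t] @ rot.T + shift
        truth = GroundTruth(
            displacement=np.abs(d),
            params={"condition": name, "sigma": cond.sigma, "drift": cond.drift,
                    "phi": cond.phi},
        )
        out[name] = (Trajectory(top, frames), truth)
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_assay_data(
    kind: str,
    params: dict | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic assay table and its ground truth.

    Supported kinds (selected ``params`` keys, all optional):

    - ``dose_response``: ``ic50`` (M, default 3.8e-8), ``n_points``,
      ``conc_range`` (M, default 5e-9..1e-5), ``noise`` (multiplicative
      sd, default 0), ``minimum``/``maximum`` raw fluorescence levels.
    - ``melt``: ``tm`` (deg C, default 68), ``width`` (deg C), ``t_range``,
      ``step``, ``noise``; optional ``tm2`` adds a second transition.
    - ``mixture``: additive mixture ``a``*A + ``b``*B of two melts, or a
      shifted-Tm sigmoid when ``interacting=True``.
    - ``absorbance``: ``protein_conc`` (M), ``loading_percent``,
      ``eps_protein``, ``eps_nucleotide``.
    - ``chromatogram``: ``areas`` per species, Gaussian peaks at
      ``centers`` (mL), ``noise``.
    - ``sec``: exact log-linear Kav law (``slope``, ``intercept``) sampled
      at the standard-protein masses, ``jitter`` (mL).
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "dose_response":
        ic50 = p.get("ic50", 3.8e-8)
        n = p.get("n_points", 10)
        lo, hi = p.get("conc_range", (5e-9, 1e-5))
        fmin = p.get("minimum", 100.0)
        fmax = p.get("maximum", 1000.0)
        noise = p.get("noise", 0.0)
        conc = np.logspace(np.log10(lo), np.log10(hi), n)
        resp = dose_response_model(conc, np.log10(ic50), fmin, fmax, -1.0)
        if noise > 0:
            resp = resp * (1.0 + noise * rng.standard_normal(n))
        df = pd.DataFrame({"conc_M": conc, "fluorescence": resp})
        return df, GroundTruth(params={"ic50": ic50, "minimum": fmin, "maximum": fmax})
    if kind == "melt":
        tm = p.get("tm", 68.0)
        width = p.get("width", 2.0)
        t0, t1 = p.get("t_range", (15.0, 95.0))
        step = p.get("step", 0.25)
        noise = p.get("noise", 0.0)
        amp = p.get("amplitude", 0.25)
        base = p.get("baseline", 0.8)
        slope = p.get("baseline_slope", 2e-4)
        t = np.arange(t0, t1 + step / 2, step)
        r = base + slope * (t - t0) + amp / (1.0 + np.exp(-(t - tm) / width))
        if "tm2" in p:
            r = r + p.get("amplitude2", amp) / (
                1.0 + np.exp(-(t - p["tm2"]) / p.get("width2", width))
            )
        if noise > 0:
            r = r + noise * rng.standard_normal(len(t))
        df = pd.DataFrame({"temperature_C": t, "ratio": r})
        return df, GroundTruth(params={"tm": tm, "tm2": p.get("tm2"), "width": width})
    if kind == "mixture":
        a = p.get("a", 0.4)
        b = p.get("b", 0.6)
        interacting = p.get("interacting", False)
        ca, _ = gen_assay_data("melt", {**p.get("component_a", {"tm": 55.0}),
                                        "noise": 0.0}, seed)
        cb, _ = gen_assay_data("melt", {**p.get("component_b", {"tm": 75.0}),
                                        "noise": 0.0}, seed)
        t = ca["temperature_C"].to_numpy()
        if interacting:
            mix_df, _ = gen_assay_data(
                "melt", {**p.get("complex", {"tm": p.get("tm_complex", 85.0)}),
                         "noise": 0.0}, seed)
            mix = mix_df["ratio"].to_numpy()
        else:
            mix = a * ca["ratio"].to_numpy() + b * cb["ratio"].to_numpy()
        noise = p.get("noise", 0.0)
        if noise > 0:
            mix = mix + noise * rng.standard_normal(len(t))
        df = pd.DataFrame(
            {"temperature_C": t, "mix": mix,
             "component_a": ca["ratio"], "component_b": cb["ratio"]}
        )
        return df, GroundTruth(params={"a": a, "b": b, "interacting": interacting})
    if kind == "absorbance":
        c_prot = p.get("protein_conc", 1.0e-4)
        loading = p.get("loading_percent", 29.0)
        eps_p = p.get("eps_protein", 8730.0)
        eps_n = p.get("eps_nucleotide", 15400.0)
        a280_after = p.get("a280_after", 0.0)
        c_nuc = loading / 100.0 * c_prot
        df = pd.DataFrame(
            [
                {
                    "a280_before": c_prot * eps_p + a280_after,
                    "a280_after": a280_after,
                    "a260_after": c_nuc * eps_n,
                    "eps_protein": eps_p,
                    "eps_nucleotide": eps_n,
                }
            ]
        )
        return df, GroundTruth(
            params={"protein_conc": c_prot, "nucleotide_conc": c_nuc,
                    "loading_percent": loading}
        )
    if kind == "chromatogram":
        areas = p.get("areas", {"AMP": 99.0, "ADP": 1.0})
        centers = p.get("centers", {"AMP": 3.0, "ADP": 5.8})
        sigma = p.get("peak_sigma", 0.15)
        noise = p.get("noise", 0.0)
        v = np.arange(0.0, p.get("v_max", 8.0), p.get("step", 0.005))
        a = np.full_like(v, p.get("baseline", 0.5))
        for name, area in areas.items():
            mu = centers[name]
            a = a + area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((v - mu) / sigma) ** 2
            )
        if noise > 0:
            a = a + noise * rng.standard_normal(len(v))
        df = pd.DataFrame({"volume_mL": v, "a260": a})
        return df, GroundTruth(params={"areas": dict(areas), "centers": dict(centers),
                                       "peak_sigma": sigma})
    if kind == "sec":
        slope = p.get("slope", -3.2)
        intercept = p.get("intercept", 6.0)
        v0 = p.get("v0", 8.0)
        vc = p.get("vc", 24.0)
        masses = p.get(
            "standards",
            {"ribonuclease A": 13700.0, "carbonic anhydrase": 29000.0,
             "ovalbumin": 44000.0, "conalbumin": 75000.0,
             "aldolase": 158000.0, "thyroglobulin": 669000.0},
        )
        jitter = p.get("jitter", 0.0)
        rows = []
        for name, mw in masses.items():
            kav = (np.log10(mw) - intercept) / slope
            ve = v0 + kav * (vc - v0)
            if jitter > 0:
                ve = ve + jitter * rng.standard_normal()
            rows.append({"standard": name, "mw_Da": mw, "ve_mL": ve})
        df = pd.DataFrame(rows)
        return df, GroundTruth(params={"slope": slope, "intercept": intercept,
                                       "v0": v0, "vc": vc})
    raise ValueError(f"unknown assay kind {kind!r}")
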