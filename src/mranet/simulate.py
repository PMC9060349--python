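"""Ground-truth regulatory network simulator.

Generates steady-state gene regulatory networks with a regulator/target
split (TFs may regulate any gene, including other TFs through feedback;
TAs have no outgoing edges), simulates basal and single-gene-perturbation
steady states, and exports MRA-ready datasets together with the true
topology.

Two kinetic modes are provided. In ``linear`` mode,

    dx/dt = b + W x - D x,

whose steady state is the exact solution of (D - W) x = b; sampled weights
are rescaled so the system operator W - D has spectral abscissa <= -0.05
(guaranteed stability) and so that the basal state and every full-knockout
state remain positive — because the steady state is affine in the perturbed
synthesis rate, positivity at the two extremes implies positivity for every
intermediate knockdown strength. In ``hill`` mode synthesis saturates,

    dx_i/dt = b_i + sum_j act(x_j) + sum_j rep(x_j) - d_i x_i,

with Hill activation w * x^h / (K^h + x^h) and repression
w * K^h / (K^h + x_j^h); all synthesis terms are nonnegative and bounded,
so trajectories stay positive and converge, and the steady state is found
by integrating from the basal condition until ||dx/dt||_inf < 1e-10.

An elementary perturbation of gene k scales its basal synthesis rate b_k by
(1 - strength): strength 1 emulates a CRISPR-style full knockout, smaller
strengths emulate shRNA-style knockdowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.linalg

from .dataset import PerturbationDataset
from .errors import InputError, SimulationError
from .matrices import GlobalResponseMatrix, LocalResponseMatrix
from .solvers import SensitivityDiagonal

__all__ = [
    "GroundTruthNetwork",
    "SimulationConfig",
    "generate_topology",
    "steady_state",
    "generate_perturbation_dataset",
    "generate_linear_mra_instance",
]

LINEAR = "linear"
HILL = "hill"

#: Required stability margin: spectral abscissa of W - D at or below this.
STABILITY_MARGIN = -0.05


@dataclass
class SimulationConfig:
    """Perturbation regime and observation noise.

    perturbation_strength in (0, 1]: 1 is a full KO (CRISPR-like), smaller
    values are partial knockdowns (shRNA-like). noise_sd is the standard
    deviation of multiplicative log-normal observation noise (0 = noise
    free).
    """

    mode: str = LINEAR
    perturbation_strength: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (LINEAR, HILL):
            raise InputError(f"unknown simulation mode {self.mode!r}")
        if not (0.0 < self.perturbation_strength <= 1.0):
            raise InputError("perturbation_strength must lie in (0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


@dataclass
class GroundTruthNetwork:
    """Signed weighted regulatory network with kinetic parameters.

    ``weights[i, j]`` is the signed strength of the edge gene j -> gene i;
    only the first ``n_tf`` genes (the regulators) have outgoing edges.
    """

    n_tf: int
    n_ta: int
    weights: np.ndarray
    synthesis: np.ndarray
    degradation: np.ndarray
    seed: int
    hill_coefficient: float = 2.0
    hill_thresholds: np.ndarray = field(default=None)  # per-regulator K
    module_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_tf + self.n_ta
        self.weights = np.asarray(self.weights, dtype=float)
        self.synthesis = np.asarray(self.synthesis, dtype=float)
        self.degradation = np.asarray(self.degradation, dtype=float)
        if self.weights.shape != (n, n):
            raise InputError("weight matrix shape does not match n_tf + n_ta")
        if np.any(self.weights[:, self.n_tf:] != 0.0):
            raise InputError("target-only genes (TAs) cannot have outgoing edges")
        if np.any(self.degradation <= 0):
            raise InputError("degradation rates must be positive")
        if self.hill_thresholds is None:
            self.hill_thresholds = self.synthesis / self.degradation
        if not self.module_ids:
            width = len(str(max(self.n_tf, self.n_ta)))
            self.module_ids = [f"TF{i+1:0{width}d}" for i in range(self.n_tf)] + [
                f"TA{i+1:0{width}d}" for i in range(self.n_ta)
            ]

    @property
    def n(self) -> int:
        return self.n_tf + self.n_ta

    def edge_frame(self) -> pd.DataFrame:
        """Ground-truth edge list: regulator, target, sign, weight."""
        rows, cols = np.nonzero(self.weights)
        return pd.DataFrame(
            {
                "regulator": [self.module_ids[j] for j in cols],
                "target": [self.module_ids[i] for i in rows],
                "sign": np.sign(self.weights[rows, cols]).astype(int),
                "weight": self.weights[rows, cols],
            }
        ).sort_values(["regulator", "target"], ignore_index=True)

    def true_local_response(self, basal: np.ndarray) -> LocalResponseMatrix:
        """Normalized Jacobian at a steady state (linear mode):
        r[i, j] = W[i, j] x_j / (d_i x_i), diagonal -1."""
        x = np.asarray(basal, dtype=float)
        r = self.weights * x[None, :] / (self.degradation[:, None] * x[:, None])
        np.fill_diagonal(r, -1.0)
        return LocalResponseMatrix(r, list(self.module_ids))


def _spectral_abscissa(net: GroundTruthNetwork) -> float:
    return float(np.max(np.real(np.linalg.eigvals(net.weights - np.diag(net.degradation)))))


def _linear_steady_state(net: GroundTruthNetwork, synthesis: np.ndarray) -> np.ndarray:
    if _spectral_abscissa(net) > STABILITY_MARGIN:
        raise SimulationError("linear system is not stable (spectral abscissa too large)")
    A = np.diag(net.degradation) - net.weights
    return scipy.linalg.solve(A, synthesis)


def _hill_rhs(net: GroundTruthNetwork, synthesis: np.ndarray, x: np.ndarray) -> np.ndarray:
    h = net.hill_coefficient
    xh = np.maximum(x, 0.0) ** h
    kh = net.hill_thresholds**h
    act_frac = xh / (kh + xh)  # per regulator j
    w_pos = np.maximum(net.weights, 0.0)
    w_neg = np.maximum(-net.weights, 0.0)
    production = synthesis + w_pos @ act_frac + w_neg @ (1.0 - act_frac)
    return production - net.degradation * x


def _hill_steady_state(
    net: GroundTruthNetwork,
    synthesis: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_time: float = 1e5,
) -> np.ndarray:
    x = x0 if x0 is not None else synthesis / net.degradation
    t_span = 50.0
    elapsed = 0.0
    while elapsed < max_time:
        sol = scipy.integrate.solve_ivp(
            lambda _, y: _hill_rhs(net, synthesis, y),
            (0.0, t_span),
            x,
            method="LSODA",
            rtol=1e-12,
            atol=1e-12,
        )
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}")
        x = sol.y[:, -1]
        elapsed += t_span
        if np.max(np.abs(_hill_rhs(net, synthesis, x))) < tol:
            return x
    raise SimulationError("hill-mode simulation did not reach a steady state")


def _steady_state(net: GroundTruthNetwork, mode: str, synthesis: np.ndarray) -> np.ndarray:
    if mode == LINEAR:
        x = _linear_steady_state(net, synthesis)
    else:
        x = _hill_steady_state(net, synthesis)
    if np.any(x < 0):
        raise SimulationError("steady state has negative activities")
    return x


def steady_state(net: GroundTruthNetwork, config: SimulationConfig) -> np.ndarray:
    """Unperturbed steady-state activity vector."""
    return _steady_state(net, config.mode, net.synthesis)


def generate_topology(
    n_tf: int,
    n_ta: int,
    mean_degree: float = 2.0,
    seed: int = 0,
    activation_fraction: float = 0.6,
) -> GroundTruthNetwork:
    """Sample a random TF/TA regulatory network.

    Edges run from a regulator (TF) to any other gene, so feedback among
    TFs is permitted while TAs have out-degree 0; ``mean_degree`` is the
    mean in-degree over all genes. Edge signs are activating with
    probability ``activation_fraction``. Linear-mode weights are rescaled
    after sampling so the system is stable with margin and so basal and
    every full-knockout steady state stay positive.
    """
    if n_tf < 2:
        raise InputError("at least two regulators (TFs) are required")
    if n_ta < 0:
        raise InputError("n_ta must be non-negative")
    n = n_tf + n_ta
    if mean_degree <= 0 or mean_degree > n_tf - 1:
        raise InputError(
            f"mean_degree {mean_degree} implies more parents than the {n_tf} "
            "available regulators allow"
        )
    rng = np.random.default_rng(seed)
    n_edges = int(round(mean_degree * n))
    # candidate (target, regulator) pairs, self-edges excluded
    candidates = np.array([(i, j) for j in range(n_tf) for i in range(n) if i != j])
    if n_edges > len(candidates):
        raise InputError("mean_degree implies more edges than available pairs")
    chosen = candidates[rng.choice(len(candidates), size=n_edges, replace=False)]
    weights = np.zeros((n, n), dtype=float)
    magnitudes = rng.uniform(0.5, 1.5, size=n_edges)
    signs = np.where(rng.random(n_edges) < activation_fraction, 1.0, -1.0)
    weights[chosen[:, 0], chosen[:, 1]] = magnitudes * signs
    synthesis = rng.uniform(2.0, 4.0, size=n)
    degradation = rng.uniform(0.5, 1.5, size=n)
    net = GroundTruthNetwork(n_tf, n_ta, weights, synthesis, degradation, seed)
    _rescale_for_viability(net)
    return net


def _rescale_for_viability(net: GroundTruthNetwork, max_halvings: int = 60) -> None:
    """Shrink edge weights until the linear system is stable with margin and
    basal plus all full-KO steady states are positive."""
    floor = 1e-3 * float(np.min(net.synthesis / net.degradation))
    for _ in range(max_halvings):
        if _spectral_abscissa(net) <= STABILITY_MARGIN:
            A = np.diag(net.degradation) - net.weights
            lu, piv = scipy.linalg.lu_factor(A)
            basal = scipy.linalg.lu_solve((lu, piv), net.synthesis)
            if np.all(basal > floor):
                # the KO'd gene itself may be dragged negative by net
                # inhibitory input; its readout is floored at 0 later
                ko_ok = True
                for k in range(net.n):
                    b = net.synthesis.copy()
                    b[k] = 0.0
                    x = scipy.linalg.lu_solve((lu, piv), b)
                    if np.any(np.delete(x, k) <= floor):
                        ko_ok = False
                        break
                if ko_ok:
                    return
        net.weights *= 0.5
    raise SimulationError("could not rescale weights to a viable stable network")


def generate_perturbation_dataset(
    net: GroundTruthNetwork, config: SimulationConfig
) -> PerturbationDataset:
    """Basal plus one single-gene-perturbation steady state per gene.

    Gene k's synthesis rate is scaled by (1 - strength); optional
    multiplicative log-normal noise is applied to every readout.
    """
    basal = steady_state(net, config)
    n = net.n
    perturbed = np.empty((n, n), dtype=float)
    for k in range(n):
        synthesis = net.synthesis.copy()
        synthesis[k] *= 1.0 - config.perturbation_strength
        if config.mode == LINEAR:
            x = _linear_steady_state(net, synthesis)
        else:
            x = _hill_steady_state(net, synthesis, x0=basal)
        perturbed[:, k] = x
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        basal = basal * np.exp(rng.normal(0.0, config.noise_sd, size=n))
        perturbed = perturbed * np.exp(rng.normal(0.0, config.noise_sd, size=(n, n)))
    # abundances are read out with a floor at zero: a fully knocked-out gene
    # with net inhibitory input has a negative linear fixed point, which the
    # measurement cannot show
    perturbed = np.maximum(perturbed, 0.0)
    return PerturbationDataset(list(net.module_ids), basal, perturbed)


def generate_linear_mra_instance(
    n: int, sparsity: float = 0.2, seed: int = 0
) -> tuple[LocalResponseMatrix, SensitivityDiagonal, GlobalResponseMatrix]:
    """Forward-constructed exact-recovery instance, R = -r^-1 P.

    Samples a sparse local response matrix (diagonal -1, ``sparsity`` is
    the fraction of nonzero off-diagonal couplings, rescaled for a spectral
    safety margin) and a diagonal P bounded away from zero, then constructs
    the exact global response. Both solvers must recover r from R exactly
    up to round-off.
    """
    if n < 2:
        raise InputError("n must be at least 2")
    if not (0.0 <= sparsity <= 1.0):
        raise InputError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(50):
        off = np.zeros((n, n))
        mask = rng.random((n, n)) < sparsity
        np.fill_diagonal(mask, False)
        k = int(mask.sum())
        off[mask] = rng.uniform(0.3, 1.0, size=k) * rng.choice([-1.0, 1.0], size=k)
        radius = float(np.max(np.abs(np.linalg.eigvals(off)))) if k else 0.0
        if radius > 0.8:
            off *= 0.8 / radius
        r_true = off - np.eye(n)
        p_diag = rng.uniform(0.5, 1.5, size=n) * rng.choice([-1.0, 1.0], size=n)
        try:
            R = -scipy.linalg.solve(r_true, np.diag(p_diag))
        except scipy.linalg.LinAlgError:
            continue
        if np.linalg.cond(R, 1) < 1e8:
            ids = [f"M{i}" for i in range(n)]
            return (
                LocalResponseMatrix(r_true, ids),
                SensitivityDiagonal(p_diag, ids),
                GlobalResponseMatrix(R, ids),
            )
    raise SimulationError("could not sample an invertible instance")
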