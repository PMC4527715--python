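"""Sparse partial-correlation coexpression network analysis.

Pipeline (order fixed): probabilistic quotient normalization -> generalized
log transform -> per-feature standardization -> sparse partial-correlation
estimation -> mean-of-matrix edge thresholding. The estimator solves the
joint symmetric lasso regression

    min_rho  1/2 sum_i w_i || x_i - sum_{j != i} rho_ij sqrt(d_j/d_i) x_j ||^2
             + lambda sum_{i<j} |rho_ij|

by cyclic coordinate descent, where rho is the symmetric partial-correlation
matrix and d_i the residual precision of variable i. Weights w_i are
iteratively set to the estimated residual precisions (two to three outer
iterations), which down-weights noisy variables.

Degree structure is validated against a discrete power law fitted by maximum
likelihood, hubs are the top fraction of nodes by degree, and edges are
tallied within/between epistasis flags and interaction classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import (
    ConfigError,
    DegenerateFitError,
    NormalizationError,
    ZeroVarianceError,
)
from .io import FoldChangeMatrix


# --------------------------------------------------------------------------
# normalization chain
# --------------------------------------------------------------------------

def pqn_normalize(
    values: pd.DataFrame, eps: float = 1e-8
) -> tuple[pd.DataFrame, np.ndarray]:
    """Probabilistic quotient normalization across samples (columns).

    The reference profile is the feature-wise median across samples; each
    sample's dilution factor is the median of its value/reference quotients
    over features whose |reference| exceeds ``eps`` (signed fold-change data
    can have near-zero references, which would make quotients unstable).
    Returns the normalized table and the per-sample factors.
    """
    if values.shape[1] < 2:
        raise ConfigError("PQN needs at least 2 samples")
    reference = values.median(axis=1)
    usable = reference.abs() > eps
    if not usable.any():
        raise NormalizationError(
            "all reference values below epsilon; PQN is ill-posed"
        )
    quotients = values.loc[usable].div(reference[usable], axis=0)
    factors = quotients.median(axis=0).to_numpy(float)
    if np.any(np.abs(factors) <= eps):
        raise NormalizationError("a sample has a near-zero dilution factor")
    return values.div(factors, axis=1), factors


def glog_scale(values: pd.DataFrame | np.ndarray, lam: float = 1.0):
    """Generalized log transform g(x) = ln((x + sqrt(x^2 + lambda)) / 2).

    Defined for negative arguments and strictly increasing; approaches
    ln(x) for large x and stabilizes variance near zero.
    """
    if lam <= 0:
        raise ConfigError("glog lambda must be > 0")
    arr = np.asarray(values, float)
    root = np.sqrt(arr**2 + lam)
    # for x < 0 the direct form cancels catastrophically; use
    # x + sqrt(x^2 + lam) = lam / (sqrt(x^2 + lam) - x)
    out = np.where(
        arr >= 0,
        np.log((arr + root) / 2.0),
        np.log(lam) - np.log(2.0 * (root - arr)),
    )
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each feature (row) to mean 0, sd 1 across samples."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    zero = sd <= 0
    if zero.any():
        raise ZeroVarianceError(
            f"zero-variance features: {list(values.index[zero])[:10]}"
        )
    return values.sub(mean, axis=0).div(sd, axis=0)


# --------------------------------------------------------------------------
# sparse partial-correlation estimation
# --------------------------------------------------------------------------

def default_tuning(n_samples: int, n_features: int, alpha: float = 0.1) -> float:
    """Canonical lasso penalty: sqrt(n) * Phi^-1(1 - alpha / (2 p^2))."""
    p = n_features
    return float(np.sqrt(n_samples) * stats.norm.ppf(1 - alpha / (2 * p**2)))


def estimate_partial_correlations(
    X: np.ndarray,
    tuning: float | None = None,
    *,
    n_outer: int = 3,
    max_sweeps: int = 500,
    tol: float = 1e-6,
) -> np.ndarray:
    """Sparse symmetric partial-correlation estimate by joint lasso regression.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
        Column-standardized data (samples in rows).
    tuning : float, optional
        L1 penalty; ``None`` uses :func:`default_tuning`. 0 gives the dense
        (unpenalized) estimate, equivalent for p < n to inverting the sample
        covariance.
    n_outer : int
        Outer iterations re-estimating residual precisions (the weights).

    Returns
    -------
    ndarray (p x p), symmetric with unit diagonal.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 3:
        raise ConfigError("partial-correlation estimation needs >= 3 samples")
    if tuning is None:
        tuning = default_tuning(n, p)
    if tuning < 0:
        raise ConfigError("tuning must be >= 0")

    norms2 = (X**2).sum(axis=0)
    rho = np.zeros((p, p))
    d = np.ones(p)  # residual precisions
    w = np.ones(p)  # regression weights ("dew": w_i = d_i)
    pairs = list(combinations(range(p), 2))

    for outer in range(n_outer):
        sq = np.sqrt(d)
        # residuals under current rho and scalings
        B = rho * (sq[None, :] / sq[:, None])  # B[i, j] = rho_ij sqrt(d_j/d_i)
        np.fill_diagonal(B, 0.0)
        R = X - X @ B.T
        for sweep in range(max_sweeps):
            max_delta = 0.0
            for i, j in pairs:
                cij = sq[j] / sq[i]
                old = rho[i, j]
                ri = R[:, i] + old * cij * X[:, j]
                rj = R[:, j] + old / cij * X[:, i]
                b = w[i] * cij * (X[:, j] @ ri) + w[j] / cij * (X[:, i] @ rj)
                a = w[i] * cij**2 * norms2[j] + w[j] / cij**2 * norms2[i]
                new = np.sign(b) * max(abs(b) - tuning, 0.0) / a
                R[:, i] = ri - new * cij * X[:, j]
                R[:, j] = rj - new / cij * X[:, i]
                rho[i, j] = rho[j, i] = new
                max_delta = max(max_delta, abs(new - old))
            if max_delta < tol:
                break
        else:
            warnings.warn(
                "partial-correlation coordinate descent did not converge; "
                "returning best iterate",
                RuntimeWarning,
            )
        d = n / (R**2).sum(axis=0)
        w = d.copy()
    np.fill_diagonal(rho, 1.0)
    return rho


# --------------------------------------------------------------------------
# network construction and analysis
# --------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    glog_lambda: float = 1.0
    tuning: float | None = None  # None -> default_tuning(n, p)
    tuning_grid: tuple[float, ...] = (0.8, 1.0, 1.2)  # multipliers
    hub_fraction: float = 0.01
    edge_rule: str = "mean_abs_offdiag"  # or "fixed_threshold"
    edge_threshold: float = 0.0  # used by fixed_threshold
    use_abs: bool = True
    apply_pqn: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hub_fraction <= 0.5:
            raise ConfigError("hub_fraction must lie in (0, 0.5]")
        if self.tuning is not None and self.tuning < 0:
            raise ConfigError("tuning must be >= 0")
        if self.edge_rule not in ("mean_abs_offdiag", "fixed_threshold"):
            raise ConfigError(f"unknown edge_rule {self.edge_rule!r}")


@dataclass
class CoexpressionNetwork:
    """A thresholded partial-correlation network with node annotations."""

    node_ids: list[str]
    pcorr: np.ndarray
    edges: pd.DataFrame  # columns: node1, node2, weight (node1 < node2 index)
    degrees: pd.Series
    annotations: pd.DataFrame | None = None  # columns: class, epistatic

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def connected_node_ids(self) -> list[str]:
        """Nodes with at least one neighbor."""
        return sorted(
            set(self.edges["node1"]) | set(self.edges["node2"]),
            key=self.node_ids.index,
        )


def build_network(
    pcorr: np.ndarray,
    node_ids: list[str],
    annotations: pd.DataFrame | None = None,
    *,
    edge_rule: str = "mean_abs_offdiag",
    edge_threshold: float = 0.0,
    use_abs: bool = True,
) -> CoexpressionNetwork:
    """Threshold a partial-correlation matrix into an edge list.

    Default rule: an edge joins i and j iff |pcorr_ij| strictly exceeds the
    mean absolute off-diagonal value of the matrix (zeros included in the
    mean). ``use_abs=False`` compares signed values instead; the
    ``fixed_threshold`` rule uses a user-supplied cutoff.
    """
    pcorr = np.asarray(pcorr, float)
    p = pcorr.shape[0]
    if pcorr.shape != (p, p) or not np.allclose(pcorr, pcorr.T, atol=1e-10):
        raise ConfigError("pcorr must be a symmetric square matrix")
    off = ~np.eye(p, dtype=bool)
    vals = np.abs(pcorr[off]) if use_abs else pcorr[off]
    if edge_rule == "mean_abs_offdiag":
        threshold = float(vals.mean()) if p > 1 else 0.0
    else:
        threshold = edge_threshold
    iu, ju = np.triu_indices(p, k=1)
    w = pcorr[iu, ju]
    crit = np.abs(w) if use_abs else w
    keep = crit > threshold
    edges = pd.DataFrame(
        {
            "node1": [node_ids[i] for i in iu[keep]],
            "node2": [node_ids[j] for j in ju[keep]],
            "weight": w[keep],
        }
    )
    deg = pd.Series(0, index=pd.Index(node_ids, name="node"), dtype=int)
    for col in ("node1", "node2"):
        counts = edges[col].value_counts()
        deg.loc[counts.index] += counts.astype(int)
    return CoexpressionNetwork(
        node_ids=list(node_ids),
        pcorr=pcorr,
        edges=edges,
        degrees=deg,
        annotations=annotations,
    )


@dataclass
class PowerLawFit:
    alpha: float
    x_min: int
    n_tail: int
    loglik: float
    regression_alpha: float
    poor_fit: bool = False


def fit_power_law(degrees, x_min: int = 1) -> PowerLawFit:
    """Discrete power-law exponent by maximum likelihood over degrees >= x_min.

    The likelihood uses the Hurwitz zeta normalization
    P(k) = k^-alpha / zeta(alpha, x_min). A log-log histogram regression
    estimate is reported alongside as a diagnostic (the classical, biased
    estimator). Fewer than two distinct degree values is degenerate.
    """
    k = np.asarray([d for d in degrees if d >= x_min], dtype=float)
    if k.size < 10:
        raise DegenerateFitError("need >= 10 nodes with degree >= x_min")
    if np.unique(k).size < 2:
        raise DegenerateFitError("all degrees equal; power-law fit degenerate")
    logsum = np.log(k).sum()

    def nll(alpha: float) -> float:
        return k.size * math.log(special.zeta(alpha, x_min)) + alpha * logsum

    res = optimize.minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded")
    alpha = float(res.x)

    # log-log degree-frequency regression diagnostic
    vals, counts = np.unique(k, return_counts=True)
    poor = vals.size < 3
    if vals.size >= 2:
        slope = np.polyfit(np.log(vals), np.log(counts), 1)[0]
        reg_alpha = -float(slope)
    else:
        reg_alpha = float("nan")
    return PowerLawFit(
        alpha=alpha,
        x_min=x_min,
        n_tail=int(k.size),
        loglik=-float(res.fun),
        regression_alpha=reg_alpha,
        poor_fit=poor,
    )


def sample_discrete_power_law(
    alpha: float, n: int, rng: np.random.Generator, k_max: int = 100_000
) -> np.ndarray:
    """Draw from P(k) ~ k^-alpha, k = 1..k_max (tail mass negligible)."""
    ks = np.arange(1, k_max + 1, dtype=float)
    pmf = ks**-alpha
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, k_max + 1), size=n, p=pmf)


@dataclass
class HubResult:
    hubs: list[str]
    jaccard: float
    wilcoxon_p: float
    grid_hub_sets: list[list[str]] = field(default_factory=list)


def find_hubs(
    network: CoexpressionNetwork,
    hub_fraction: float = 0.01,
    grid_networks: list[CoexpressionNetwork] | None = None,
) -> HubResult:
    """Top-degree hubs, their stability across a tuning grid, and significance.

    Hubs are the ceil(hub_fraction * n_nodes) highest-degree nodes (ties by
    node id). The Jaccard score is the mean pairwise Jaccard index between
    hub sets recomputed on the tuning-grid networks (1.0 by convention for a
    single network). Significance is a two-sided Wilcoxon rank-sum test of
    hub vs non-hub degrees.
    """
    if network.n_edges == 0:
        raise ConfigError("cannot identify hubs in an edgeless network")

    def top_nodes(net: CoexpressionNetwork) -> list[str]:
        n_hubs = math.ceil(hub_fraction * len(net.node_ids))
        ranked = sorted(
            net.degrees.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return [node for node, _ in ranked[:n_hubs]]

    hubs = top_nodes(network)
    nets = grid_networks if grid_networks else [network]
    hub_sets = [set(top_nodes(net)) for net in nets]
    if len(hub_sets) == 1:
        jaccard = 1.0
    else:
        scores = []
        for s1, s2 in combinations(hub_sets, 2):
            union = s1 | s2
            scores.append(len(s1 & s2) / len(union) if union else 1.0)
        jaccard = float(np.mean(scores))
    hub_mask = network.degrees.index.isin(hubs)
    hub_deg = network.degrees[hub_mask].to_numpy()
    rest_deg = network.degrees[~hub_mask].to_numpy()
    if rest_deg.size == 0:
        wilcoxon_p = float("nan")
    else:
        wilcoxon_p = float(stats.ranksums(hub_deg, rest_deg).pvalue)
    return HubResult(
        hubs=hubs,
        jaccard=jaccard,
        wilcoxon_p=wilcoxon_p,
        grid_hub_sets=[sorted(s) for s in hub_sets],
    )


def classify_edges(network: CoexpressionNetwork) -> dict:
    """Tally edges by the epistasis flags and interaction classes of endpoints.

    Returns two partitions of the edge set: (both epistatic, neither, mixed)
    and (within-class, between-class); each sums to the edge count.
    """
    ann = network.annotations
    if ann is None:
        raise ConfigError("node annotations required for edge classification")
    tallies = {
        "both_epistatic": 0,
        "neither_epistatic": 0,
        "mixed_epistatic": 0,
        "within_class": 0,
        "between_class": 0,
        "n_edges": network.n_edges,
    }
    for n1, n2 in zip(network.edges["node1"], network.edges["node2"]):
        if n1 not in ann.index or n2 not in ann.index:
            raise ConfigError(f"edge endpoint without annotation: {n1}, {n2}")
        e1, e2 = bool(ann.loc[n1, "epistatic"]), bool(ann.loc[n2, "epistatic"])
        if e1 and e2:
            tallies["both_epistatic"] += 1
        elif not e1 and not e2:
            tallies["neither_epistatic"] += 1
        else:
            tallies["mixed_epistatic"] += 1
        if ann.loc[n1, "class"] == ann.loc[n2, "class"]:
            tallies["within_class"] += 1
        else:
            tallies["between_class"] += 1
    return tallies


# --------------------------------------------------------------------------
# model-style wrapper
# --------------------------------------------------------------------------

class SparsePartialCorrelationModel:
    """Coexpression-network model over a fold-change matrix.

    Runs the fixed normalization chain (PQN -> glog -> standardize) on
    construction; :meth:`fit` estimates the sparse partial-correlation
    matrix and thresholds it into a network, optionally across a tuning
    grid for hub-stability analysis.
    """

    def __init__(self, data: FoldChangeMatrix, config: NetworkConfig | None = None):
        self.data = data
        self.config = config or NetworkConfig()
        values = data.values
        if self.config.apply_pqn:
            values, self.pqn_factors = pqn_normalize(values)
        else:
            self.pqn_factors = np.ones(values.shape[1])
        values = glog_scale(values, self.config.glog_lambda)
        self.processed = standardize(values)

    def fit(
        self, annotations: pd.DataFrame | None = None
    ) -> "CoexpressionNetworkResults":
        cfg = self.config
        X = self.processed.to_numpy(float).T  # samples x features
        n, p = X.shape
        base_tuning = cfg.tuning if cfg.tuning is not None else default_tuning(n, p)

        def one(t: float) -> CoexpressionNetwork:
            pc = estimate_partial_correlations(X, t)
            return build_network(
                pc,
                list(self.processed.index),
                annotations,
                edge_rule=cfg.edge_rule,
                edge_threshold=cfg.edge_threshold,
                use_abs=cfg.use_abs,
            )

        network = one(base_tuning)
        grid = [
            network if m == 1.0 else one(base_tuning * m) for m in cfg.tuning_grid
        ]
        return CoexpressionNetworkResults(
            model=self, network=network, grid_networks=grid, tuning=base_tuning
        )


class CoexpressionNetworkResults:
    def __init__(
        self,
        model: SparsePartialCorrelationModel,
        network: CoexpressionNetwork,
        grid_networks: list[CoexpressionNetwork],
        tuning: float,
    ):
        self.model = model
        self.network = network
        self.grid_networks = grid_networks
        self.tuning = tuning

    def power_law(self, x_min: int = 1) -> PowerLawFit:
        degrees = self.network.degrees[self.network.degrees >= 1]
        return fit_power_law(degrees.to_numpy(), x_min=x_min)

    def hubs(self) -> HubResult:
        return find_hubs(
            self.network, self.model.config.hub_fraction, self.grid_networks
        )

    def edge_classes(self) -> dict:
        return classify_edges(self.network)

    def summary(self) -> str:
        net = self.network
        connected = net.connected_node_ids()
        lines = [
            "Sparse partial-correlation coexpression network",
            "=" * 48,
            f"nodes: {len(net.node_ids)} ({len(connected)} with >= 1 neighbor)",
            f"edges: {net.n_edges}",
            f"tuning: {self.tuning:.4g}",
        ]
        if net.n_edges:
            hub = self.hubs()
            lines.append(
                f"hubs (top {self.model.config.hub_fraction:.0%} by degree): "
                f"{len(hub.hubs)}; grid Jaccard {hub.jaccard:.2f}; "
                f"Wilcoxon p {hub.wilcoxon_p:.3g}"
            )
            if net.annotations is not None:
                t = self.edge_classes()
                lines.append(
                    f"edges both/neither/mixed epistatic: "
                    f"{t['both_epistatic']}/{t['neither_epistatic']}/"
                    f"{t['mixed_epistatic']}; within/between class: "
                    f"{t['within_class']}/{t['between_class']}"
                )
        return "\n".join(lines)

    def tables(self) -> dict[str, pd.DataFrame]:
        net = self.network
        edges = net.edges.copy()
        ann = net.annotations
        if ann is not None and len(edges):
            pair_type, class_pair = [], []
            for n1, n2 in zip(edges["node1"], edges["node2"]):
                e1, e2 = bool(ann.loc[n1, "epistatic"]), bool(ann.loc[n2, "epistatic"])
                pair_type.append(
                    "both" if e1 and e2 else ("neither" if not (e1 or e2) else "mixed")
                )
                class_pair.append(
                    "within" if ann.loc[n1, "class"] == ann.loc[n2, "class"]
                    else "between"
                )
            edges["epistasis_pair"] = pair_type
            edges["class_pair"] = class_pair
        nodes = pd.DataFrame(
            {"node": net.node_ids, "degree": net.degrees.to_numpy()}
        )
        if ann is not None:
            nodes["class"] = [ann.loc[n, "class"] for n in net.node_ids]
            nodes["epistatic"] = [bool(ann.loc[n, "epistatic"]) for n in net.node_ids]
        return {"network_edges": edges, "network_nodes": nodes}
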