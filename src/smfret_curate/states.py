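"""FRET-state distribution analysis.

Kept-frame FRET values from accepted trajectories are pooled per condition
and modelled as a K-component univariate Gaussian mixture (default K = 3:
low / medium / high FRET).  Fitting is maximum likelihood via
expectation–maximization with multiple seeded restarts; the best
log-likelihood wins and the run is deterministic for a fixed seed.  Values
are assigned to states by maximum posterior responsibility (hard
assignment), yielding global and per-cell occupancy proportions that can be
compared across conditions or pipelines with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

_SD_FLOOR = 1e-4


class DegenerateMixtureError(RuntimeError):
    """EM collapsed a component onto a point mass in every restart."""


@dataclass
class StateModel:
    """A fitted Gaussian mixture over pooled FRET values.

    ``components`` is a list of (weight, mean, sd) sorted by mean ascending.
    ``ll_history`` records the log-likelihood at every EM iteration of the
    winning restart (non-decreasing by construction).
    """

    components: list[tuple[float, float, float]]
    n_values: int
    condition: str = ""
    log_likelihood: float = float("nan")
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        sd = np.array([c[2] for c in self.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(sd <= 0):
            raise ValueError("standard deviations must be positive")
        means = [c[1] for c in self.components]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("components must be sorted by mean ascending")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    def to_dict(self) -> dict:
        return {
            "components": [
                {"weight": w, "mean": m, "sd": s} for w, m, s in self.components
            ],
            "n_values": self.n_values,
            "condition": self.condition,
            "log_likelihood": self.log_likelihood,
        }


@dataclass
class CellProportions:
    """Fraction of one cell's kept frames assigned to each state."""

    cell_id: str
    fractions: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.n_frames > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("per-cell fractions must sum to 1")


def pool_fret(traces, region_labels: dict[str, str], accepted_regions) -> np.ndarray:
    """Concatenate efficiencies of traces whose region label is accepted."""
    values, _ = pool_fret_with_cells(traces, region_labels, accepted_regions)
    return values


def pool_fret_with_cells(
    traces, region_labels: dict[str, str], accepted_regions
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled efficiencies plus the cell id of every pooled value."""
    accepted = set(accepted_regions)
    vals: list[np.ndarray] = []
    cells: list[np.ndarray] = []
    for tr in traces:
        if region_labels.get(tr.traj_id) in accepted:
            vals.append(np.asarray(tr.efficiency, dtype=float))
            cells.append(np.repeat(tr.cell_id, len(tr)))
    if not vals:
        return np.empty(0), np.empty(0, dtype=object)
    return np.concatenate(vals), np.concatenate(cells)


def _em_run(values, weights, means, sds, max_iter, tol):
    """One EM run; returns (weights, means, sds, ll, history).

    Raises :class:`DegenerateMixtureError` if a component's sd collapses.
    The log-likelihood is asserted non-decreasing at every iteration.
    """
    x = values[:, None]
    ll_prev = -np.inf
    history: list[float] = []
    for _ in range(max_iter):
        log_comp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((x - means[None, :]) / sds[None, :]) ** 2
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        assert ll >= ll_prev - 1e-7 * max(1.0, abs(ll_prev)), "EM log-likelihood decreased"
        history.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk <= 0):
            raise DegenerateMixtureError("empty component")
        weights = nk / len(values)
        means = (resp * x).sum(axis=0) / nk
        var = (resp * (x - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < _SD_FLOOR):
            raise DegenerateMixtureError("component sd collapsed")
        if ll - ll_prev < tol:
            break
        ll_prev = ll
    return weights, means, sds, ll, history


def fit_states(
    values,
    k: int = 3,
    seed: int = 0,
    condition: str = "",
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> StateModel:
    """Fit a k-component Gaussian mixture to pooled FRET values by EM.

    Initialisation uses quantile-spaced means, the pooled standard
    deviation, and uniform weights; subsequent restarts jitter the means
    with noise drawn from a generator seeded by ``seed`` (deterministic for
    a fixed seed).  The restart with the best final log-likelihood wins.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10 * k:
        raise ValueError(f"need at least {10 * k} values to fit {k} states, got {len(x)}")
    rng = np.random.default_rng(seed)
    q = (np.arange(k) + 0.5) / k
    base_means = np.quantile(x, q)
    pooled_sd = max(float(np.std(x)), _SD_FLOOR * 10)
    best = None
    for restart in range(n_restarts):
        means = base_means.copy()
        if restart > 0:
            means = np.sort(means + rng.normal(0.0, pooled_sd / 4, size=k))
        weights = np.full(k, 1.0 / k)
        sds = np.full(k, pooled_sd)
        try:
            fitted = _em_run(x, weights, means, sds, max_iter, tol)
        except DegenerateMixtureError:
            continue
        if best is None or fitted[3] > best[3]:
            best = fitted
    if best is None:
        raise DegenerateMixtureError(
            f"all {n_restarts} EM restarts degenerated for k={k}, n={len(x)}"
        )
    weights, means, sds, ll, history = best
    order = np.argsort(means)
    components = [
        (float(weights[i]), float(means[i]), float(sds[i])) for i in order
    ]
    return StateModel(
        components=components,
        n_values=len(x),
        condition=condition,
        log_likelihood=ll,
        ll_history=history,
    )


def responsibilities(model: StateModel, values) -> np.ndarray:
    """(n, k) posterior probability of each component for each value."""
    x = np.asarray(values, dtype=float)[:, None]
    w, m, s = model.weights, model.means, model.sds
    log_comp = (
        np.log(w)[None, :]
        - 0.5 * np.log(2 * np.pi)
        - np.log(s)[None, :]
        - 0.5 * ((x - m[None, :]) / s[None, :]) ** 2
    )
    return np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])


def state_proportions(
    model: StateModel, values, cell_ids=None
) -> tuple[np.ndarray, list[CellProportions]]:
    """State-occupancy proportions by hard (max-posterior) assignment.

    Returns the global proportions and, when ``cell_ids`` is given, the
    per-cell breakdown (fractions sum to 1 within each cell).
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        return np.zeros(model.k), []
    assign = np.argmax(responsibilities(model, x), axis=1)
    global_props = np.bincount(assign, minlength=model.k) / len(x)
    per_cell: list[CellProportions] = []
    if cell_ids is not None:
        cell_ids = np.asarray(cell_ids)
        for cell in sorted(set(cell_ids.tolist())):
            sel = cell_ids == cell
            counts = np.bincount(assign[sel], minlength=model.k)
            per_cell.append(
                CellProportions(
                    cell_id=str(cell),
                    fractions=counts / counts.sum(),
                    n_frames=int(sel.sum()),
                )
            )
    return global_props, per_cell


def compare_groups(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test on per-cell state proportions.

    Returns (t, p).  Two identical zero-variance groups yield (0.0, 1.0) by
    convention rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells")
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # both groups constant
        if a[0] == b[0]:
            return 0.0, 1.0
        return (np.inf if a[0] > b[0] else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def build_histogram(
    values,
    bin_width: float = 0.02,
    value_range: tuple[float, float] = (-0.2, 1.2),
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-edge histogram of FRET values; counts cover in-range values only."""
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    lo, hi = value_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    x = np.asarray(values, dtype=float)
    counts, _ = np.histogram(x, bins=edges)
    return edges, counts
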