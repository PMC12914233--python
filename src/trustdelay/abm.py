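"""Agent-based simulation of the AI-trust / health-care-delay feedback loop.

One agent per survey respondent, embedded in a Watts-Strogatz small-world
network (n = 2460, mean degree 4, rewiring probability 0.2). Each simulated
day every agent

1. computes a delay probability from its current trust and usage frequency
   (and chronic status) with the survey-derived logistic model,
2. makes a Bernoulli delay decision,
3. updates trust/frequency: personal outcome (delay: trust -0.2, frequency
   -0.3; no delay: trust +0.1), peer influence (attraction toward the mean
   neighbour trust; a penalty when most neighbours delayed today), a global
   daily trust decay, and the active intervention,
4. clamps both scores to the [1, 5] scale.

Population statistics (delay rate, mean trust, mean trust by baseline-risk
stratum) are recorded each day *before* the updates, and aggregated over
independent trials. Three interventions are layered on the baseline rules:
*broadcast* (a fixed daily trust penalty, modelling trust-eroding
messaging), *reward* (a trust/frequency bonus every other day for agents
with no delay in the current window) and *rewire* (periodic redirection of
a fraction of edges toward the highest-trust decile, modelling opinion-
leader amplification).

The delay model used by the agents operates on the 1-5 scale (survey level
0, "never used", maps to 1); see :func:`published_delay_model`.

The peer-influence gain, peer-delay penalty and daily trust decay are not
survey-identified; their defaults were fixed once by a grid search against
the three baseline trajectory anchors (day-1 delay rate 10.6%, day-14
delay rate 9.5%, day-14 mean trust 1.49) and are documented in
docs/methods.md. All other simulated quantities are out-of-sample model
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.special import expit

from .regression import LogisticFit, Z95, fit_logistic
from .survey import calibrate_intercept

__all__ = [
    "ABMConfig",
    "AgentState",
    "Network",
    "TrajectorySummary",
    "STRATEGIES",
    "published_delay_model",
    "refit_delay_model",
    "build_network",
    "initialize_agents",
    "daily_step",
    "apply_broadcast",
    "apply_reward",
    "apply_rewire",
    "run_experiment",
    "compare_strategies",
]

STRATEGIES = ("baseline", "broadcast", "reward", "rewire")
ABM_PREDICTORS = ["trust", "frequency", "chronic"]


@dataclass
class ABMConfig:
    """Simulation parameters; defaults are the calibrated study conditions."""

    n_agents: int = 2460
    degree_k: int = 4
    rewire_p: float = 0.2
    days: int = 14
    trials: int = 100
    strategy: str = "baseline"
    # behavioural update magnitudes
    delta_delay_trust: float = 0.2
    delta_delay_freq: float = 0.3
    delta_nodelay_trust: float = 0.1
    # structural-vulnerability initialisation
    risk_threshold: float = 0.20
    init_reduction: float = 1.0
    # interventions
    broadcast_penalty: float = 0.10
    reward_magnitude: float = 0.05
    reward_interval_days: int = 2
    rewire_interval_days: int = 5
    rewire_fraction: float = 0.10
    # peer influence and decay (grid-calibrated once; see module docstring)
    peer_gain: float = 0.1
    peer_delay_penalty: float = 0.05
    peer_delay_threshold: float = 0.5
    trust_decay: float = 0.125
    # sensitivity-sweep override: shift initial trust to this mean
    initial_trust_mean: float | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1 or self.trials < 1:
            raise ValueError("days and trials must be >= 1")
        if self.degree_k % 2 or not 0 < self.degree_k < self.n_agents:
            raise ValueError("degree_k must be even and in (0, n_agents)")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in ("delta_delay_trust", "delta_delay_freq",
                     "delta_nodelay_trust", "broadcast_penalty",
                     "reward_magnitude", "peer_gain", "peer_delay_penalty",
                     "trust_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AgentState:
    """Vectorised per-agent state (one array entry per agent)."""

    trust: np.ndarray           # float in [1, 5]
    frequency: np.ndarray       # float in [1, 5]
    chronic: np.ndarray         # 0/1
    baseline_risk: np.ndarray   # predicted delay prob at init, pre-reduction
    high_risk: np.ndarray       # baseline_risk > threshold
    delayed_today: np.ndarray = field(default=None)
    delay_history: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.trust.size

    def copy(self) -> "AgentState":
        return AgentState(self.trust.copy(), self.frequency.copy(),
                          self.chronic, self.baseline_risk, self.high_risk)


class Network:
    """Undirected graph as a mutable edge array with a cached adjacency."""

    def __init__(self, n: int, edges: np.ndarray):
        self.n = n
        self.edges = np.asarray(edges, dtype=np.int64)
        self._rebuild()

    def _rebuild(self) -> None:
        m = len(self.edges)
        A = sp.csr_matrix(
            (np.ones(m), (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n, self.n))
        self.adjacency = A + A.T
        self.degrees = np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_mean(self, values: np.ndarray,
                      fallback: np.ndarray) -> np.ndarray:
        """Mean of ``values`` over each agent's neighbours.

        Isolated agents get their ``fallback`` entry (so peer terms vanish).
        """
        sums = self.adjacency @ values
        deg = np.maximum(self.degrees, 1)
        return np.where(self.degrees > 0, sums / deg, fallback)

    def to_edgelist(self, path) -> None:
        np.savetxt(path, self.edges, fmt="%d")


def build_network(n: int, k: int, p: float, seed: int) -> Network:
    """Watts-Strogatz small-world graph: ring lattice with ``k`` nearest
    neighbours, each lattice edge rewired with probability ``p`` (no
    self-loops, no duplicate edges). Exactly ``n*k/2`` edges."""
    if k % 2 or not 0 < k < n:
        raise ValueError("k must be even and satisfy 0 < k < n")
    if not 0 <= p <= 1:
        raise ValueError("rewiring probability must lie in [0, 1]")
    g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    return Network(n, np.array(g.edges(), dtype=np.int64))


def published_delay_model(records: pd.DataFrame,
                          beta_trust: float = np.log(1.09),
                          beta_freq: float = np.log(1.40),
                          beta_chronic: float = np.log(1.42),
                          target_rate: float = 0.116) -> LogisticFit:
    """The three-predictor delay model on the agents' 1-5 operating scale.

    Uses the published odds ratios for trust, frequency and chronic status
    and calibrates the intercept on the mapped (level 0 -> 1) covariates so
    that the mean predicted delay probability over the respondents equals
    the survey delay prevalence. Using the published coefficients rather
    than a per-sample refit keeps the agents' decision rule identical
    across survey samples of the same population.
    """
    T = np.maximum(records["trust"].to_numpy(float), 1.0)
    F = np.maximum(records["frequency"].to_numpy(float), 1.0)
    C = records["chronic"].to_numpy(float)
    betas = (beta_trust, beta_freq, beta_chronic)
    b0 = calibrate_intercept(betas, np.column_stack([T, F, C]), target_rate)
    k = 4
    return LogisticFit(
        outcome="delay", predictors=list(ABM_PREDICTORS),
        coefficients=np.array([b0, *betas]),
        standard_errors=np.full(k, np.nan),
        n_obs=len(records), converged=True,
        status="published coefficients, calibrated intercept",
        metadata={"scale": "mapped 1-5", "target_rate": target_rate})


def refit_delay_model(records: pd.DataFrame) -> LogisticFit:
    """Refit the three-predictor delay model on the mapped 1-5 covariates."""
    work = records.copy()
    work["trust"] = np.maximum(work["trust"].to_numpy(float), 1.0)
    work["frequency"] = np.maximum(work["frequency"].to_numpy(float), 1.0)
    fit = fit_logistic(work, "delay", ABM_PREDICTORS)
    fit.metadata["scale"] = "mapped 1-5"
    return fit


def _model_coefs(fit: LogisticFit) -> np.ndarray:
    if list(fit.predictors) != ABM_PREDICTORS:
        raise ValueError(
            f"agent delay model must have predictors {ABM_PREDICTORS}, "
            f"got {fit.predictors}")
    return np.asarray(fit.coefficients, float)


def _predict(coefs: np.ndarray, trust, freq, chronic) -> np.ndarray:
    return expit(coefs[0] + coefs[1] * trust + coefs[2] * freq
                 + coefs[3] * chronic)


def initialize_agents(records: pd.DataFrame, fit: LogisticFit,
                      config: ABMConfig) -> AgentState:
    """Create agent state from survey records.

    Trust and frequency are copied with level 0 mapped to 1 (the simulation
    operates on [1, 5]); ``baseline_risk`` is the model's prediction on the
    mapped values, and agents strictly above ``risk_threshold`` receive the
    structural-vulnerability reduction on both scores (clamped to >= 1).
    With ``config.initial_trust_mean`` set, the mapped trust distribution is
    location-shifted to that mean (then clamped) before risk is computed.
    """
    if len(records) != config.n_agents:
        raise ValueError(
            f"record count {len(records)} != configured n_agents "
            f"{config.n_agents}")
    coefs = _model_coefs(fit)
    trust = np.maximum(records["trust"].to_numpy(float), 1.0)
    freq = np.maximum(records["frequency"].to_numpy(float), 1.0)
    chronic = records["chronic"].to_numpy(float)
    if config.initial_trust_mean is not None:
        trust = np.clip(
            trust + (config.initial_trust_mean - trust.mean()), 1.0, 5.0)
    risk = _predict(coefs, trust, freq, chronic)
    high = risk > config.risk_threshold
    trust = np.where(high,
                     np.maximum(trust - config.init_reduction, 1.0), trust)
    freq = np.where(high,
                    np.maximum(freq - config.init_reduction, 1.0), freq)
    return AgentState(trust, freq, chronic, risk, high)


def apply_broadcast(trust_next: np.ndarray, config: ABMConfig) -> np.ndarray:
    """Daily fixed trust penalty (clamping is deferred to the step clamp)."""
    if config.broadcast_penalty < 0:
        raise ValueError("broadcast_penalty must be >= 0")
    return trust_next - config.broadcast_penalty


def apply_reward(trust_next: np.ndarray, freq_next: np.ndarray,
                 window_clean: np.ndarray, day: int, config: ABMConfig
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trust/frequency bonus for agents with no delay in the closing window.

    Applied on days divisible by ``reward_interval_days``; the window
    covers the days since the previous reward day, inclusive of today.
    Returns the updated arrays and the window accumulator (reset on reward
    days).
    """
    if day % config.reward_interval_days == 0:
        trust_next = np.where(window_clean,
                              trust_next + config.reward_magnitude,
                              trust_next)
        freq_next = np.where(window_clean,
                             freq_next + config.reward_magnitude, freq_next)
        window_clean = np.ones_like(window_clean)
    return trust_next, freq_next, window_clean


def apply_rewire(network: Network, trust: np.ndarray, day: int,
                 config: ABMConfig, rng: np.random.Generator) -> Network:
    """Redirect a fraction of edges toward the highest-trust decile.

    On days divisible by ``rewire_interval_days``, ``rewire_fraction`` of
    the edges are each re-attached: one randomly chosen endpoint is
    replaced by an agent drawn uniformly from the top trust decile (ties
    broken by lowest agent id). Self-loops and duplicate edges are avoided
    by redrawing (up to 10 attempts; the original edge is kept on failure),
    so the edge count is conserved.
    """
    if day % config.rewire_interval_days != 0:
        return network
    n = network.n
    n_top = max(1, n // 10)
    order = np.lexsort((np.arange(n), -trust))   # stable: trust desc, id asc
    top = order[:n_top]
    m = network.n_edges
    n_rewire = int(round(config.rewire_fraction * m))
    if n_rewire == 0:
        return network
    chosen = rng.choice(m, size=n_rewire, replace=False)
    edges = network.edges.copy()
    edge_set = {(min(u, v), max(u, v)) for u, v in edges}
    for ei in chosen:
        u, v = edges[ei]
        keep = int(v if rng.integers(2) == 0 else u)
        old_key = (min(u, v), max(u, v))
        for _ in range(10):
            w = int(top[rng.integers(n_top)])
            if w == keep:
                continue
            new_key = (min(keep, w), max(keep, w))
            if new_key in edge_set:
                continue
            edge_set.discard(old_key)
            edge_set.add(new_key)
            edges[ei] = (keep, w)
            break
    return Network(n, edges)


def daily_step(agents: AgentState, network: Network, fit: LogisticFit,
               config: ABMConfig, day: int, rng: np.random.Generator,
               window_clean: np.ndarray | None = None
               ) -> tuple[Network, np.ndarray, dict]:
    """Advance the population by one day (synchronous update).

    Returns the (possibly rewired) network, the reward-window accumulator,
    and the day's statistics. Statistics describe the start-of-day state:
    the delay rate uses today's decisions, trust summaries the pre-update
    scores. Update order per agent: personal outcome, peer terms (start-of-
    day trust, same-day neighbour delays), global decay, intervention,
    clamp to [1, 5].
    """
    coefs = _model_coefs(fit)
    if window_clean is None:
        window_clean = np.ones(agents.n, dtype=bool)
    T, F, C = agents.trust, agents.frequency, agents.chronic

    p = _predict(coefs, T, F, C)
    delayed = rng.random(agents.n) < p
    stats = {
        "day": day,
        "delay_rate": float(delayed.mean()),
        "mean_trust": float(T.mean()),
        "mean_trust_high_risk": float(T[agents.high_risk].mean())
        if agents.high_risk.any() else float("nan"),
        "mean_trust_low_risk": float(T[~agents.high_risk].mean())
        if (~agents.high_risk).any() else float("nan"),
    }

    # (1) personal outcome
    T_next = np.where(delayed, T - config.delta_delay_trust,
                      T + config.delta_nodelay_trust)
    F_next = np.where(delayed, F - config.delta_delay_freq, F)
    # (2) peer context: attraction to neighbour mean, penalty when most
    #     neighbours delayed today
    nbr_trust = network.neighbor_mean(T, fallback=T)
    T_next = T_next + config.peer_gain * (nbr_trust - T)
    frac_delayed = network.neighbor_mean(delayed.astype(float),
                                         fallback=np.zeros(agents.n))
    T_next = np.where(frac_delayed > config.peer_delay_threshold,
                      T_next - config.peer_delay_penalty, T_next)
    # (3) global decay
    T_next = T_next - config.trust_decay
    # (4) intervention hook
    if config.strategy == "broadcast":
        T_next = apply_broadcast(T_next, config)
    elif config.strategy == "reward":
        window_clean = window_clean & ~delayed
        T_next, F_next, window_clean = apply_reward(
            T_next, F_next, window_clean, day, config)
    elif config.strategy == "rewire":
        network = apply_rewire(network, T, day, config, rng)
    # (5) clamp
    agents.trust = np.clip(T_next, 1.0, 5.0)
    agents.frequency = np.clip(F_next, 1.0, 5.0)
    agents.delayed_today = delayed
    agents.delay_history.append(delayed)
    return network, window_clean, stats


@dataclass
class TrajectorySummary:
    """Per-day population statistics aggregated over trials."""

    strategy: str
    days: int
    trials: int
    delay_rate: np.ndarray            # (days,) mean over trials
    delay_rate_se: np.ndarray
    mean_trust: np.ndarray
    mean_trust_se: np.ndarray
    mean_trust_high_risk: np.ndarray
    mean_trust_low_risk: np.ndarray
    total_delays: int                 # pooled over agents x days x trials
    total_agent_days: int
    per_trial_delay_rate: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": np.arange(1, self.days + 1),
            "delay_rate": self.delay_rate,
            "delay_rate_se": self.delay_rate_se,
            "mean_trust": self.mean_trust,
            "mean_trust_se": self.mean_trust_se,
            "mean_trust_high_risk": self.mean_trust_high_risk,
            "mean_trust_low_risk": self.mean_trust_low_risk,
        })

    def to_dict(self) -> dict:
        df = self.to_frame()
        return {"strategy": self.strategy, "trials": self.trials,
                "days": self.days,
                "total_delays": self.total_delays,
                "total_agent_days": self.total_agent_days,
                "trajectory": df.to_dict("records")}


def run_experiment(records: pd.DataFrame, fit: LogisticFit,
                   config: ABMConfig) -> TrajectorySummary:
    """Run ``config.trials`` independent trials and aggregate by day.

    Trial ``t`` uses seed ``base_seed + t`` for all of its randomness
    (network construction, delay decisions, rewiring); agents and the
    network are rebuilt per trial, so the full experiment is reproducible
    from (records, fit, config).
    """
    agents0 = initialize_agents(records, fit, config)
    keys = ["delay_rate", "mean_trust", "mean_trust_high_risk",
            "mean_trust_low_risk"]
    acc = {k: np.zeros((config.trials, config.days)) for k in keys}
    total_delays = 0
    for t in range(config.trials):
        rng = np.random.default_rng(config.base_seed + t)
        net = build_network(config.n_agents, config.degree_k,
                            config.rewire_p,
                            seed=int(rng.integers(2**31)))
        agents = agents0.copy()
        window = None
        for day in range(1, config.days + 1):
            net, window, stats = daily_step(agents, net, fit, config, day,
                                            rng, window)
            for k in keys:
                acc[k][t, day - 1] = stats[k]
            total_delays += int(np.sum(agents.delayed_today))
    sqrt_t = np.sqrt(config.trials)
    return TrajectorySummary(
        strategy=config.strategy, days=config.days, trials=config.trials,
        delay_rate=acc["delay_rate"].mean(axis=0),
        delay_rate_se=acc["delay_rate"].std(axis=0, ddof=1) / sqrt_t
        if config.trials > 1 else np.zeros(config.days),
        mean_trust=acc["mean_trust"].mean(axis=0),
        mean_trust_se=acc["mean_trust"].std(axis=0, ddof=1) / sqrt_t
        if config.trials > 1 else np.zeros(config.days),
        mean_trust_high_risk=acc["mean_trust_high_risk"].mean(axis=0),
        mean_trust_low_risk=acc["mean_trust_low_risk"].mean(axis=0),
        total_delays=total_delays,
        total_agent_days=config.trials * config.days * config.n_agents,
        per_trial_delay_rate=acc["delay_rate"],
    )


def compare_strategies(results: dict[str, TrajectorySummary]
                       ) -> pd.DataFrame:
    """Odds ratios of delay for each intervention arm versus baseline.

    Pools the agent-day delay indicators of every arm (agent x day x
    trial) and fits a logistic regression of delay on strategy indicator
    variables with the baseline arm as reference. The fit uses the
    aggregated binomial representation, which is exactly equivalent to the
    individual-level logistic regression for a saturated categorical
    design.
    """
    if "baseline" not in results:
        raise ValueError("a 'baseline' arm is required as the reference")
    arms = ["baseline"] + [s for s in results if s != "baseline"]
    succ = np.array([results[s].total_delays for s in arms], float)
    fail = np.array([results[s].total_agent_days for s in arms]) - succ
    X = np.zeros((len(arms), len(arms) - 1))
    for j in range(1, len(arms)):
        X[j, j - 1] = 1.0
    Xc = sm.add_constant(X, has_constant="add")
    import warnings
    with warnings.catch_warnings():
        # the aggregated design is saturated (zero residual df), which
        # statsmodels flags even though the MLE is exact and well-defined
        warnings.simplefilter("ignore")
        res = sm.GLM(np.column_stack([succ, fail]), Xc,
                     family=sm.families.Binomial()).fit()
    rows = []
    for j, s in enumerate(arms[1:], start=1):
        beta, se = res.params[j], res.bse[j]
        rows.append({
            "strategy": s,
            "or": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - Z95 * se)),
            "ci_high": float(np.exp(beta + Z95 * se)),
            "p": float(res.pvalues[j]),
            "delay_rate": float(succ[j] / (succ[j] + fail[j])),
            "n_agent_days": int(succ[j] + fail[j]),
        })
    return pd.DataFrame(rows)
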