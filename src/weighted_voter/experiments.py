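"""Config-driven experiment sweeps with theory overlays.

An experiment sweeps one protocol variable (population size, initial
supporters, worse-site quality, lag, degree, edge probability, geometric
radius, or gamma noise shape), runs seeded replicates at each value, and
emits a per-replicate results table plus an overlay table holding the
matching closed forms (exact fixation probability, time bounds, exact mean
consensus time where computable, and the branching-process fixation
approximation for noisy measurements).  Overlays are always computed
through the theory/noisy modules, never re-derived here.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .graphs import (
    complete_eta,
    degree_stats,
    expanded_cycle_eta,
    make_graph,
    parse_graph_spec,
    with_eta,
)
from .noisy import (
    GammaDist,
    PointMass,
    QualityDist,
    fixation_large_N,
    parse_quality,
    rate_lambda,
    solve_extinction,
)
from .simulator import SimOptions, run_many
from .theory import (
    NoiseFreeModel,
    best_of_n_bounds,
    exact_mean_consensus_time,
    fixation_prob,
    time_bounds,
)

_GRAPH_HEADS = {
    "complete",
    "excycle",
    "expanded_cycle",
    "rr",
    "random_regular",
    "er",
    "erdos_renyi",
    "rgg",
    "random_geometric",
}

_SWEEPS = {"none", "N", "k", "q_b", "lag_mean", "d", "p", "r", "shape"}

RESULT_COLUMNS = [
    "experiment_id",
    "sweep",
    "value",
    "rep",
    "seed",
    "winner",
    "consensus_time",
    "n_updates",
    "capped",
]


def parse_spec(spec: str):
    """Parse a graph or quality spec string into its descriptor object."""
    head = spec.partition(":")[0].strip().lower()
    if head in _GRAPH_HEADS:
        return parse_graph_spec(spec)
    return parse_quality(spec)


@dataclass(frozen=True)
class ExperimentConfig:
    """One sweep: graph family, varied parameter, qualities, init rule.

    ``init`` is ``"k=<int>"`` (count), ``"k=<float in (0,1)>"`` (fraction of
    N), or ``"counts=c1,c2,..."`` for best-of-n.  ``qualities`` (best-first)
    overrides the two-option ``quality_a``/``quality_b`` pair.
    """

    experiment_id: str
    graph: str
    sweep: str = "none"
    values: tuple = (None,)
    quality_a: str = "point:1.0"
    quality_b: str = "point:0.9"
    qualities: tuple | None = None
    init: str = "k=0.5"
    reps: int = 1000
    base_seed: int = 0
    lag_mean: float = 0.0
    dynamic: bool = False
    init_mode: str = "fresh"
    graph_per_rep: bool = False
    max_events: int = 10**7

    def __post_init__(self):
        if self.sweep not in _SWEEPS:
            raise ConfigError(f"sweep: unknown variable {self.sweep!r}")
        if len(self.values) == 0:
            raise ConfigError("values: must be nonempty")
        if self.reps < 1:
            raise ConfigError("reps: must be >= 1")
        parse_graph_spec(self.graph)
        for q in self.quality_specs():
            if not isinstance(q, QualityDist):
                raise ConfigError("qualities: not a quality distribution")

    def quality_specs(self) -> list[QualityDist]:
        if self.qualities is not None:
            return [parse_quality(q) for q in self.qualities]
        return [parse_quality(self.quality_a), parse_quality(self.quality_b)]

    def parse_init(self, n: int) -> list[int]:
        """Resolve the init rule into per-option counts for population n."""
        rule = self.init.strip()
        key, eq, val = rule.partition("=")
        if key == "k" and eq:
            try:
                x = float(val)
            except ValueError as exc:
                raise ConfigError(f"init: bad number in {rule!r}") from exc
            k = int(round(x * n)) if 0 < x < 1 else int(x)
            if not (0 <= k <= n):
                raise ConfigError(f"init: k={k} outside [0, {n}]")
            return [k, n - k]
        if key == "counts" and eq:
            try:
                counts = [int(c) for c in val.split(",")]
            except ValueError as exc:
                raise ConfigError(f"init: bad counts in {rule!r}") from exc
            if sum(counts) != n:
                raise ConfigError(
                    f"init: counts sum to {sum(counts)}, expected N={n}"
                )
            return counts
        if key == "equal" and eq:
            try:
                n_opts = int(val)
            except ValueError as exc:
                raise ConfigError(f"init: bad option count in {rule!r}") from exc
            if n_opts < 2 or n % n_opts != 0:
                raise ConfigError(
                    f"init: equal split needs N divisible by {n_opts}, got N={n}"
                )
            return [n // n_opts] * n_opts
        raise ConfigError(f"init: cannot parse {rule!r}")

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("values", "qualities"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_json(self) -> str:
        d = asdict(self)
        d["values"] = list(self.values)
        if self.qualities is not None:
            d["qualities"] = list(self.qualities)
        return json.dumps(d, sort_keys=True, indent=2)


def config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _apply_sweep(config: ExperimentConfig, value):
    """Materialise (graph spec, quality specs, lag) for one sweep value."""
    gspec = parse_graph_spec(config.graph)
    specs = config.quality_specs()
    lag = config.lag_mean
    sw = config.sweep
    if sw == "N":
        gspec = replace(gspec, n=int(value))
    elif sw == "d":
        gspec = replace(gspec, d=int(value))
    elif sw == "p":
        gspec = replace(gspec, p=float(value))
    elif sw == "r":
        gspec = replace(gspec, r=float(value))
    elif sw == "lag_mean":
        lag = float(value)
    elif sw == "q_b":
        if not isinstance(specs[1], PointMass):
            raise ConfigError("q_b sweep requires a point-mass quality_b")
        specs = [specs[0], PointMass(float(value))]
    elif sw == "shape":
        out = []
        for s in specs:
            if not isinstance(s, GammaDist):
                raise ConfigError("shape sweep requires gamma qualities")
            out.append(GammaDist.from_mean(float(value), s.mean))
        specs = out
    elif sw in {"none", "k"}:
        pass
    return gspec, specs, lag


def _overlay_row(config, value, gspec, specs, counts) -> dict:
    """Theory overlay for one sweep point, where applicable."""
    n = gspec.n
    row: dict = {"value": value, "N": n, "k": counts[0]}
    noise_free = all(isinstance(s, PointMass) for s in specs)
    if noise_free and len(specs) == 2:
        model = NoiseFreeModel.from_qualities(
            n, specs[0].value, specs[1].value, counts[0]
        )
        p_best = fixation_prob(model)
        if specs[0].value < specs[1].value:  # option 0 was not the better one
            p_best = 1.0 - p_best
        row["fixation_theory"] = p_best
        row["fixation_kind"] = "birth_death_exact"
        if model.lam > 1:
            row["complete_bound"] = 2.0 * (1.0 + math.log(n)) / (model.lam - 1.0)
            if gspec.family == "complete" and 1 <= counts[0] <= n - 1:
                row["time_exact"] = exact_mean_consensus_time(
                    n, model.lam, counts[0]
                ).expected_time
                row["eta"] = complete_eta(n)
            elif gspec.family == "expanded_cycle" and gspec.d:
                eta = expanded_cycle_eta(n, gspec.d)
                row["eta"] = eta
                g = make_graph(gspec)
                stats = with_eta(
                    degree_stats(g), eta, "closed_form_expanded_cycle"
                )
                row["regular_bound"] = time_bounds(
                    n, model.lam, stats
                ).regular_bound
    elif noise_free and len(specs) > 2:
        lam2 = specs[0].value / specs[1].value
        if lam2 > 1:
            b = best_of_n_bounds(n, counts, lam2)
            row["fixation_theory"] = 1.0 - b.cor1_error_bound
            row["fixation_kind"] = "cor1_lower_bound"
            row["fixation_heuristic"] = 1.0 - b.conj1_error_heuristic
    else:
        lam = rate_lambda(specs[1])
        sol = solve_extinction(specs[0], lam)
        row["fixation_theory"] = fixation_large_N(sol, max(counts[0], 1))
        row["fixation_kind"] = "branching_large_N"
        row["pi"] = sol.pi
    return row


def run_experiment(config: ExperimentConfig):
    """Run the sweep; returns (results table, overlay table).

    One row per (sweep value, replicate); deterministic from
    ``config.base_seed`` (per-value base seeds derive from it via a stable
    seed-sequence hash, and per-replicate seeds from those).
    """
    rows = []
    overlay = []
    for vi, value in enumerate(config.values):
        gspec, specs, lag = _apply_sweep(config, value)
        n = gspec.n
        if config.sweep == "k":
            counts = [int(value), n - int(value)]
            if not (0 <= counts[0] <= n):
                raise ConfigError(f"k={value} outside [0, {n}]")
        else:
            counts = config.parse_init(n)
        if len(counts) != len(specs):
            raise ConfigError(
                f"init gives {len(counts)} options but {len(specs)} qualities"
            )
        assignment = np.repeat(np.arange(len(counts)), counts)
        options = SimOptions(
            lag_mean=lag,
            dynamic=config.dynamic,
            max_events=config.max_events,
            init_mode=config.init_mode,
        )
        value_seed = int(
            np.random.SeedSequence((config.base_seed, vi)).generate_state(1)[0]
        )
        random_family = gspec.family in {
            "random_regular",
            "erdos_renyi",
            "random_geometric",
        }
        if random_family and config.graph_per_rep:
            graph, factory = None, (lambda r, gs=gspec: make_graph(gs, r))
        elif random_family:
            g_rng = np.random.default_rng(
                np.random.SeedSequence((config.base_seed, vi, 1))
            )
            graph, factory = make_graph(gspec, g_rng), None
        else:
            graph, factory = make_graph(gspec), None
        summary = run_many(
            graph,
            assignment,
            specs,
            reps=config.reps,
            base_seed=value_seed,
            options=options,
            graph_factory=factory,
        )
        for rep, res in enumerate(summary.results):
            rows.append(
                {
                    "experiment_id": config.experiment_id,
                    "sweep": config.sweep,
                    "value": value,
                    "rep": rep,
                    "seed": res.seed,
                    "winner": -1 if res.winner is None else res.winner,
                    "consensus_time": res.consensus_time,
                    "n_updates": res.n_updates,
                    "capped": int(res.capped),
                }
            )
        overlay.append(_overlay_row(config, value, gspec, specs, counts))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS), pd.DataFrame(overlay)


def write_results(table: pd.DataFrame, path) -> None:
    try:
        table.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"could not write results to {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"could not read results from {path}: {exc}") from exc


def write_summary(config: ExperimentConfig, results: pd.DataFrame, path) -> None:
    """Companion JSON: config, its hash, package version, per-value stats."""
    per_value = []
    for value, grp in results.groupby("value", dropna=False):
        done = grp[grp["capped"] == 0]
        freq_best = float((grp["winner"] == 0).mean())
        per_value.append(
            {
                "value": None if pd.isna(value) else value,
                "reps": int(len(grp)),
                "fixation_freq_best": freq_best,
                "fixation_se_best": math.sqrt(
                    freq_best * (1 - freq_best) / len(grp)
                ),
                "mean_time": float(done["consensus_time"].mean())
                if len(done)
                else None,
                "time_q1": float(done["consensus_time"].quantile(0.25))
                if len(done)
                else None,
                "time_q3": float(done["consensus_time"].quantile(0.75))
                if len(done)
                else None,
            }
        )
    payload = {
        "config": json.loads(config.to_json()),
        "config_hash": config_hash(config),
        "version": __version__,
        "per_value": per_value,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def builtin_experiments() -> dict:
    """Reduced-scale templates for the standard protocol sweeps."""
    t = {}
    t["fig2"] = ExperimentConfig(
        experiment_id="fig2",
        graph="complete:n=100",
        sweep="N",
        values=(10, 20, 50, 100),
        init="k=0.5",
        reps=200,
    )
    t["fig4"] = ExperimentConfig(
        experiment_id="fig4",
        graph="complete:n=100",
        sweep="k",
        values=(1, 5, 10, 20, 50, 80, 99),
        reps=200,
    )
    t["fig5"] = ExperimentConfig(
        experiment_id="fig5",
        graph="complete:n=50",
        sweep="q_b",
        values=(0.2, 0.4, 0.6, 0.8, 1.0),
        init="k=0.5",
        reps=200,
    )
    t["fig6"] = ExperimentConfig(
        experiment_id="fig6",
        graph="complete:n=50",
        sweep="lag_mean",
        values=(0.0, 0.2, 1.0, 5.0),
        init="k=0.1",
        reps=200,
    )
    t["fig8"] = ExperimentConfig(
        experiment_id="fig8",
        graph="complete:n=20",
        sweep="N",
        values=(20, 40, 60),
        qualities=tuple(f"point:{q/10:g}" for q in range(10, 0, -1)),
        init="equal=10",
        reps=200,
    )
    t["fig9"] = ExperimentConfig(
        experiment_id="fig9",
        graph="excycle:n=100,d=4",
        sweep="d",
        values=(2, 4, 8, 16),
        init="k=0.5",
        reps=100,
    )
    t["fig10"] = ExperimentConfig(
        experiment_id="fig10",
        graph="rr:n=50,d=4",
        sweep="d",
        values=(4, 8, 12),
        init="k=0.1",
        reps=200,
        graph_per_rep=True,
    )
    t["fig11"] = ExperimentConfig(
        experiment_id="fig11",
        graph="rr:n=50,d=4",
        sweep="d",
        values=(4, 8),
        init="k=0.1",
        reps=200,
        dynamic=True,
    )
    t["fig12"] = ExperimentConfig(
        experiment_id="fig12",
        graph="er:n=50,p=0.2",
        sweep="p",
        values=(0.1, 0.2, 0.3, 0.4),
        init="k=0.1",
        reps=200,
    )
    t["fig13"] = ExperimentConfig(
        experiment_id="fig13",
        graph="rgg:n=50,r=0.25",
        sweep="r",
        values=(0.2, 0.25, 0.3),
        init="k=0.1",
        reps=200,
    )
    t["fig14"] = ExperimentConfig(
        experiment_id="fig14",
        graph="complete:n=100",
        sweep="shape",
        values=(0.5, 1.0, 2.0, 5.0),
        quality_a="gamma:shape=2,mean=1.0",
        quality_b="gamma:shape=2,mean=0.9",
        init="k=1",
        reps=400,
        init_mode="size_biased",
    )
    return t
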