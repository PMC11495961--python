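"""Individual-balanced bootstrap null for the group startle statistic.

The observed group statistic is the unweighted mean over males of each
male's mean Δ across his display elements of a given intensity class.
The null asks: is that statistic larger (or smaller) than it would be at
random moments of the same recordings?  One null replicate is built by
drawing, for every male independently, as many random *eligible* frames
(with replacement, uniformly, pooled across that male's bouts) as that
male contributed Δ records, evaluating Δ at each sampled frame as a
pseudo-event start under the identical window rule, averaging within
male, and then averaging the male means.  Repeating this B times
(default 1000) yields the sampling distribution, its 2.5/97.5%
quantiles, and an add-one empirical p-value (two-sided by default).

A frame is eligible iff the full baseline and post segments around it
lie inside one bout with RD defined throughout — exactly the strict
policy that admits an observed Δ record, so observed and null
statistics share their construction.

On small problems the Monte-Carlo null can be replaced by exhaustive
enumeration of every unordered with-replacement draw, which serves as
an exact reference in tests.

Robustness sweeps re-run the test over a grid of post-window sizes
(default 4–50) and baseline sizes (default 5, 10, 15, 20), each grid
cell with a seed derived deterministically from the master seed and the
cell coordinates; leave-one-out re-runs it with each male omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb

import numpy as np
import pandas as pd

from .cleaning import compute_body_metrics
from .exceptions import ConfigurationError, EmptyGroupError, ParameterError
from .io import Dataset, INTENSITY_CLASSES, STATUSES
from .kinematics import (
    MissingPolicy,
    RDSeries,
    STRICT,
    WindowSpec,
    delta_at_all_frames,
    peri_event_deltas,
    relative_displacement,
)

logger = logging.getLogger(__name__)

TAILS = ("two_sided", "upper", "lower")


@dataclass(frozen=True)
class InferenceConfig:
    """Bootstrap-test settings and robustness grids."""

    reps: int = 1000
    alpha: float = 0.05
    tail: str = "two_sided"
    post_sizes: tuple[int, ...] = tuple(range(4, 51))
    baseline_sizes: tuple[int, ...] = (5, 10, 15, 20)
    default_baseline: int = 10
    statistic: str = "mean"  # "mean" -> delta_mean, "max" -> delta_max
    method: str = "monte_carlo"  # or "exhaustive"
    exhaustive_limit: int = 200_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ParameterError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.tail not in TAILS:
            raise ParameterError(f"tail must be one of {TAILS}")
        if self.statistic not in ("mean", "max"):
            raise ParameterError("statistic must be 'mean' or 'max'")
        if self.method not in ("monte_carlo", "exhaustive"):
            raise ParameterError("method must be 'monte_carlo' or 'exhaustive'")

    @property
    def delta_column(self) -> str:
        return "delta_mean" if self.statistic == "mean" else "delta_max"


def compute_rd(dataset: Dataset) -> dict[str, RDSeries]:
    """Body metrics + relative displacement for every bout of a dataset."""
    metrics = compute_body_metrics(dataset.tracks)
    return relative_displacement(dataset.tracks, metrics)


def eligible_frames(
    rd_map: dict[str, RDSeries],
    window: WindowSpec,
    male_of_bout: pd.Series,
) -> dict[str, list[tuple[str, int]]]:
    """Per-male eligible pseudo-event frames, pooled across bouts."""
    out: dict[str, list[tuple[str, int]]] = {}
    for bout_id, rd in rd_map.items():
        male = male_of_bout.get(bout_id)
        if male is None:
            continue
        _, mask = delta_at_all_frames(rd, window)
        frames = np.flatnonzero(mask)
        out.setdefault(male, []).extend((bout_id, int(f)) for f in frames)
    return out


def _eligible_delta_values(
    rd_map: dict[str, RDSeries],
    window: WindowSpec,
    male_of_bout: pd.Series,
    statistic: str,
    males: list[str],
) -> dict[str, np.ndarray]:
    """Δ evaluated at every eligible frame, concatenated per male."""
    pools: dict[str, list[np.ndarray]] = {m: [] for m in males}
    for bout_id, rd in rd_map.items():
        male = male_of_bout.get(bout_id)
        if male not in pools:
            continue
        delta, mask = delta_at_all_frames(rd, window, statistic)
        pools[male].append(delta[mask])
    return {
        m: (np.concatenate(vals) if vals else np.empty(0)) for m, vals in pools.items()
    }


def empirical_p(observed: float, null: np.ndarray, tail: str = "two_sided") -> float:
    """Add-one empirical p-value of ``observed`` against ``null``.

    ``p_upper = (1 + #{null >= observed}) / (B + 1)`` and symmetrically
    for the lower tail; the two-sided value doubles the smaller tail and
    caps at 1.
    """
    if len(null) == 0:
        raise ParameterError("null distribution is empty")
    b = len(null)
    p_upper = (1 + int((null >= observed).sum())) / (b + 1)
    p_lower = (1 + int((null <= observed).sum())) / (b + 1)
    if tail == "upper":
        return min(1.0, p_upper)
    if tail == "lower":
        return min(1.0, p_lower)
    return min(1.0, 2.0 * min(p_upper, p_lower))


@dataclass
class NullDistribution:
    """Bootstrap sampling distribution of the group Δ statistic."""

    status: str
    element_class: str
    window: WindowSpec
    statistic: str
    replicates: np.ndarray
    observed: float
    p_value: float
    alpha: float
    tail: str
    method: str
    seed: object
    individuals: pd.DataFrame  # male_id, n_elements, n_eligible, mean
    excluded: list[str]
    q025: float = field(init=False)
    q975: float = field(init=False)

    def __post_init__(self) -> None:
        self.q025 = float(np.quantile(self.replicates, 0.025))
        self.q975 = float(np.quantile(self.replicates, 0.975))

    @property
    def significant(self) -> bool:
        """Observed statistic outside the null's central 95% band
        (tail-appropriate for one-sided tests)."""
        if self.tail == "upper":
            return self.observed > float(np.quantile(self.replicates, 1 - self.alpha))
        if self.tail == "lower":
            return self.observed < float(np.quantile(self.replicates, self.alpha))
        return not (self.q025 <= self.observed <= self.q975)


def _per_male_null_means(
    values: np.ndarray, n_draw: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.integers(0, len(values), size=(reps, n_draw))
    return values[idx].mean(axis=1)


def _exhaustive_grand_means(
    per_male: list[tuple[np.ndarray, int]], limit: int
) -> np.ndarray:
    """Every unordered with-replacement draw, averaged across males."""
    total = 1
    for values, n_draw in per_male:
        total *= comb(len(values) + n_draw - 1, n_draw)
        if total > limit:
            raise ConfigurationError(
                f"exhaustive null would need {total}+ combinations "
                f"(limit {limit}); use the Monte-Carlo method"
            )
    male_means = []
    for values, n_draw in per_male:
        means = np.array(
            [np.mean([values[i] for i in combo])
             for combo in combinations_with_replacement(range(len(values)), n_draw)]
        )
        male_means.append(means)
    grid = male_means[0]
    for arr in male_means[1:]:
        grid = (grid[:, None] + arr[None, :]).ravel()
    return grid / len(male_means)


def bootstrap_null(
    dataset: Dataset,
    status_group: str,
    element_class: str,
    window: WindowSpec,
    config: InferenceConfig,
    rd_map: dict[str, RDSeries] | None = None,
    policy: MissingPolicy = STRICT,
    exclude_males: tuple[str, ...] = (),
    seed: object = None,
    balance_class: str | None = None,
) -> NullDistribution:
    """Bootstrap null for one status group and element class.

    ``balance_class`` controls which element counts set the per-male
    number of sampled frames; by default the counts of the class under
    test.  ``seed`` (int or ``numpy`` SeedSequence) overrides
    ``config.seed``.
    """
    if status_group not in STATUSES:
        raise ParameterError(f"unknown status {status_group!r}")
    if rd_map is None:
        rd_map = compute_rd(dataset)
    males = dataset.males_with_status(status_group)
    males = [m for m in males if m not in exclude_males]
    if not males:
        raise EmptyGroupError(f"no males with status {status_group!r}")

    balance_class = balance_class or element_class
    deltas, _ = peri_event_deltas(
        rd_map,
        dataset.events.loc[dataset.events["intensity_class"] == element_class],
        dataset.metadata,
        window,
        policy,
    )
    if balance_class == element_class:
        balance_deltas = deltas
    else:
        balance_deltas, _ = peri_event_deltas(
            rd_map,
            dataset.events.loc[dataset.events["intensity_class"] == balance_class],
            dataset.metadata,
            window,
            policy,
        )

    column = config.delta_column
    pools = _eligible_delta_values(
        rd_map, window, dataset.male_of_bout(), config.statistic, males
    )

    rows, excluded = [], []
    for male in males:
        obs = deltas.loc[deltas["male_id"] == male, column]
        n_balance = int((balance_deltas["male_id"] == male).sum())
        n_eligible = len(pools[male])
        if len(obs) == 0 or n_balance == 0 or n_eligible == 0:
            excluded.append(male)
            logger.warning(
                "bootstrap_null: excluding male %s (%d records, %d balance "
                "elements, %d eligible frames)", male, len(obs), n_balance, n_eligible,
            )
            continue
        rows.append(
            {"male_id": male, "n_elements": len(obs), "n_draw": n_balance,
             "n_eligible": n_eligible, "mean": float(obs.mean())}
        )
    if not rows:
        raise EmptyGroupError(
            f"status {status_group!r}: no male has both {element_class} elements "
            "and eligible frames"
        )
    individuals = pd.DataFrame(rows)
    observed = float(individuals["mean"].mean())

    if seed is None:
        seed = config.seed
    per_male = [(pools[r.male_id], int(r.n_draw)) for r in individuals.itertuples()]
    if config.method == "exhaustive":
        replicates = _exhaustive_grand_means(per_male, config.exhaustive_limit)
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros(config.reps)
        for values, n_draw in per_male:
            acc += _per_male_null_means(values, n_draw, config.reps, rng)
        replicates = acc / len(per_male)

    p = empirical_p(observed, replicates, config.tail)
    return NullDistribution(
        status=status_group,
        element_class=element_class,
        window=window,
        statistic=config.statistic,
        replicates=replicates,
        observed=observed,
        p_value=p,
        alpha=config.alpha,
        tail=config.tail,
        method=config.method,
        seed=seed,
        individuals=individuals,
        excluded=excluded,
    )


def _cell_seed(config: InferenceConfig, *coords: int) -> np.random.SeedSequence:
    """Deterministic per-cell seed so any sweep cell can be re-run alone."""
    entropy = 0 if config.seed is None else config.seed
    return np.random.SeedSequence(entropy=entropy, spawn_key=tuple(coords))


@dataclass
class SweepResult:
    """Grid of bootstrap tests over post and baseline sizes."""

    table: pd.DataFrame
    config: InferenceConfig

    def significant_fraction(self, **filters) -> float:
        sub = self.table
        for key, value in filters.items():
            sub = sub.loc[sub[key] == value]
        return float(sub["significant"].mean()) if len(sub) else float("nan")


def window_sweep(
    dataset: Dataset,
    config: InferenceConfig,
    statuses: tuple[str, ...] = STATUSES,
    classes: tuple[str, ...] = INTENSITY_CLASSES,
    rd_map: dict[str, RDSeries] | None = None,
) -> SweepResult:
    """Re-run the bootstrap test over the (post × baseline) grid.

    One row per (status, intensity class, post size, baseline size);
    baselines default to {5, 10, 15, 20} with the post sweep repeated at
    each.  Each cell draws its null from a seed derived from the master
    seed and the cell coordinates.
    """
    if rd_map is None:
        rd_map = compute_rd(dataset)
    baselines = list(dict.fromkeys(config.baseline_sizes))
    rows = []
    for ci, element_class in enumerate(classes):
        for si, status in enumerate(statuses):
            for baseline in baselines:
                for post in config.post_sizes:
                    window = WindowSpec(baseline=baseline, post=post)
                    try:
                        null = bootstrap_null(
                            dataset, status, element_class, window, config,
                            rd_map=rd_map,
                            seed=_cell_seed(config, si, ci, baseline, post),
                        )
                    except EmptyGroupError:
                        logger.warning(
                            "window_sweep: skipping empty cell %s/%s b=%d w=%d",
                            status, element_class, baseline, post,
                        )
                        continue
                    rows.append(
                        {"status": status, "intensity_class": element_class,
                         "baseline": baseline, "post": post,
                         "observed": null.observed, "q025": null.q025,
                         "q975": null.q975, "null_mean": float(null.replicates.mean()),
                         "p_value": null.p_value, "significant": null.significant,
                         "n_individuals": len(null.individuals)}
                    )
    return SweepResult(table=pd.DataFrame(rows), config=config)


def leave_one_out(
    dataset: Dataset,
    status_group: str,
    element_class: str,
    window: WindowSpec,
    config: InferenceConfig,
    rd_map: dict[str, RDSeries] | None = None,
) -> pd.DataFrame:
    """Stability table: the test re-run with each male omitted in turn.

    Flags sign changes of the observed statistic and changes of the
    significance verdict relative to the full-group fit.
    """
    males = dataset.males_with_status(status_group)
    if len(males) < 2:
        raise ParameterError(
            f"leave-one-out needs >= 2 males in group {status_group!r}"
        )
    if rd_map is None:
        rd_map = compute_rd(dataset)
    full = bootstrap_null(
        dataset, status_group, element_class, window, config, rd_map=rd_map,
        seed=_cell_seed(config, 0),
    )
    rows = []
    for male in males:
        # one shared seed across omissions: common random numbers isolate
        # the effect of the omitted male (and omitting either of two
        # identical males yields identical rows)
        null = bootstrap_null(
            dataset, status_group, element_class, window, config, rd_map=rd_map,
            exclude_males=(male,), seed=_cell_seed(config, 1),
        )
        rows.append(
            {"omitted_male": male, "observed": null.observed,
             "p_value": null.p_value, "q025": null.q025, "q975": null.q975,
             "significant": null.significant,
             "sign_changed": np.sign(null.observed) != np.sign(full.observed),
             "significance_changed": null.significant != full.significant}
        )
    return pd.DataFrame(rows)
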