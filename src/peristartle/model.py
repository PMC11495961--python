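"""Model/Results front end over the peri-event startle analysis.

:class:`StartleResponseModel` binds a :class:`~peristartle.io.Dataset`
to an analysis configuration (intensity class, window, Δ statistic,
missing policy, cleaning thresholds); its :meth:`fit` runs the
individual-balanced bootstrap for both status groups and returns a
:class:`StartleResponseResults` carrying the observed statistics, null
distributions, p-values and a ``summary()`` table.  Robustness sweeps
and leave-one-out stability hang off the results object.

    >>> model = StartleResponseModel(dataset, intensity_class="high")
    >>> res = model.fit(reps=1000, seed=7)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .cleaning import BodyMetrics, compute_body_metrics, filter_jumps
from .inference import (
    InferenceConfig,
    NullDistribution,
    SweepResult,
    bootstrap_null,
    leave_one_out,
    window_sweep,
)
from .io import Dataset, STATUSES
from .kinematics import (
    GroupStatistic,
    MissingPolicy,
    STRICT,
    WindowSpec,
    group_statistic,
    peri_event_deltas,
    relative_displacement,
)


class StartleResponseModel:
    """Peri-event startle analysis of one dataset.

    Parameters
    ----------
    dataset
        Joined tracks/annotations/exits dataset.
    intensity_class
        Display-element class under test (``"high"`` or ``"low"``).
    window
        Baseline/post window specification (default 10/10 frames).
    statistic
        ``"mean"`` for Δ_mean (default) or ``"max"`` for Δ_max.
    policy
        Missing-frame policy for observed Δ records.
    clean
        When true (default) the tracks are velocity-filtered before any
        kinematics: frame-to-frame jumps above ``hard`` body heights are
        invalidated and jumps in ``(soft, hard]`` flagged.
    """

    def __init__(
        self,
        dataset: Dataset,
        intensity_class: str = "high",
        window: WindowSpec = WindowSpec(10, 10),
        statistic: str = "mean",
        policy: MissingPolicy = STRICT,
        clean: bool = True,
        hard: float = 0.5,
        soft: float = 0.25,
    ) -> None:
        self.dataset = dataset
        self.intensity_class = intensity_class
        self.window = window
        self.statistic = statistic
        self.policy = policy
        metrics = compute_body_metrics(dataset.tracks)
        if clean:
            tracks, self.cleaning_report = filter_jumps(
                dataset.tracks, metrics, hard=hard, soft=soft
            )
            metrics = compute_body_metrics(tracks)
        else:
            tracks, self.cleaning_report = dataset.tracks, None
        self.body_metrics: BodyMetrics = metrics
        self._tracks = tracks
        self.rd_map = relative_displacement(tracks, metrics)

    @classmethod
    def from_directory(cls, path, **kwargs) -> "StartleResponseModel":
        from .io import read_dataset

        return cls(read_dataset(path), **kwargs)

    def deltas(self, window: WindowSpec | None = None) -> pd.DataFrame:
        """Observed Δ records for the model's intensity class."""
        window = window or self.window
        events = self.dataset.events
        events = events.loc[events["intensity_class"] == self.intensity_class]
        records, _ = peri_event_deltas(
            self.rd_map, events, self.dataset.metadata, window, self.policy
        )
        return records

    def fit(
        self,
        reps: int = 1000,
        alpha: float = 0.05,
        tail: str = "two_sided",
        seed: int | None = None,
        method: str = "monte_carlo",
        statuses: tuple[str, ...] = STATUSES,
    ) -> "StartleResponseResults":
        config = InferenceConfig(
            reps=reps, alpha=alpha, tail=tail, seed=seed, method=method,
            statistic=self.statistic,
            default_baseline=self.window.baseline,
        )
        nulls = {
            status: bootstrap_null(
                self.dataset, status, self.intensity_class, self.window, config,
                rd_map=self.rd_map, policy=self.policy,
                seed=None if seed is None else seed + i,
            )
            for i, status in enumerate(statuses)
        }
        deltas = self.deltas()
        stats = group_statistic(deltas, config.delta_column)
        return StartleResponseResults(
            model=self, config=config, nulls=nulls, delta_records=deltas,
            group_stats=stats,
        )


@dataclass
class StartleResponseResults:
    """Fitted startle-response contrast with its bootstrap nulls."""

    model: StartleResponseModel
    config: InferenceConfig
    nulls: dict[str, NullDistribution]
    delta_records: pd.DataFrame
    group_stats: GroupStatistic

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for status, null in self.nulls.items():
            rows.append(
                {
                    "status": status,
                    "intensity_class": null.element_class,
                    "baseline": null.window.baseline,
                    "post": null.window.post,
                    "n_individuals": len(null.individuals),
                    "n_elements": int(null.individuals["n_elements"].sum()),
                    "observed_delta": null.observed,
                    "q025": null.q025,
                    "q975": null.q975,
                    "p_value": null.p_value,
                    "significant": null.significant,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit report."""
        window = self.model.window
        lines = [
            "Peri-event startle response: individual-balanced bootstrap",
            f"  statistic: delta_{self.model.statistic}  "
            f"(baseline {window.baseline} / post {window.post} frames)",
            f"  intensity class: {self.model.intensity_class};  "
            f"B = {self.config.reps} replicates;  tail = {self.config.tail}",
        ]
        for row in self.summary_frame().itertuples():
            verdict = "significant" if row.significant else "not significant"
            lines.append(
                f"  {row.status:<12} n={row.n_individuals:>2} males, "
                f"{row.n_elements:>4} elements: observed delta = "
                f"{row.observed_delta:+.4f}, null 95% "
                f"[{row.q025:+.4f}, {row.q975:+.4f}], p = {row.p_value:.4g} "
                f"({verdict})"
            )
        return "\n".join(lines)

    def window_sweep(
        self,
        post_sizes: tuple[int, ...] | None = None,
        baseline_sizes: tuple[int, ...] | None = None,
        classes: tuple[str, ...] | None = None,
    ) -> SweepResult:
        config = self.config
        if post_sizes is not None:
            config = replace(config, post_sizes=tuple(post_sizes))
        if baseline_sizes is not None:
            config = replace(config, baseline_sizes=tuple(baseline_sizes))
        return window_sweep(
            self.model.dataset, config,
            classes=classes or (self.model.intensity_class,),
            rd_map=self.model.rd_map,
        )

    def leave_one_out(self, status: str) -> pd.DataFrame:
        return leave_one_out(
            self.model.dataset, status, self.model.intensity_class,
            self.model.window, self.config, rd_map=self.model.rd_map,
        )
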