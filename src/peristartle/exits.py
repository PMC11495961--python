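"""Bower-exit scoring, the status contrast, and annotation agreement.

An exit (the receiver leaving the space between the bower walls) is
attributed to the most recent display element whose start frame
precedes it within the same bout; an element's binary outcome is 1 iff
at least one exit is attributed to it.  Whether bower owners and
subordinate males differ in their per-element exit probability is
tested, by default, with a cluster permutation test that treats males
as the exchangeable units: the statistic is the difference between
status groups in the unweighted mean of per-male exit proportions, and
the null permutes status labels across males while preserving each
male's outcome vector.  An optional mixed-model variant fits the
binomial GLMM (status fixed effect, random intercepts for male and
date) through R's lme4 and compares it against the null model without
status by a likelihood-ratio test.

The module also quantifies agreement between automatic and manual
keypoint annotations: per-keypoint Euclidean error (pixels and
body-height fractions) and per-axis correlation.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import BodyMetrics
from .exceptions import (
    EmptyComparisonError,
    EmptyGroupError,
    InsufficientClustersError,
)
from .inference import empirical_p
from .io import Dataset

logger = logging.getLogger(__name__)


def score_exits(
    events: pd.DataFrame,
    exits: pd.DataFrame,
    class_filter: str | None = "high",
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Binary exit outcome per display element.

    Each exit is attributed to the most recent element of the same bout
    whose start frame does not come after it (optionally within
    ``max_lag`` frames); exits preceding every element of their bout are
    logged as unattributed.  The returned table is restricted to
    ``class_filter`` (``None`` keeps all classes) and carries one row
    per element with ``outcome`` ∈ {0, 1}.
    """
    events = events.sort_values(["bout_id", "start_frame"], kind="stable")
    events = events.reset_index(drop=True)
    outcome = np.zeros(len(events), dtype=int)
    starts_by_bout = {
        bout: (group.index.to_numpy(), group["start_frame"].to_numpy())
        for bout, group in events.groupby("bout_id")
    }
    n_unattributed = 0
    for exit_row in exits.itertuples():
        entry = starts_by_bout.get(exit_row.bout_id)
        if entry is None:
            n_unattributed += 1
            continue
        idx, starts = entry
        pos = int(np.searchsorted(starts, exit_row.frame, side="right")) - 1
        if pos < 0:
            n_unattributed += 1
            logger.warning(
                "score_exits: exit at frame %d in bout %s precedes every element",
                exit_row.frame, exit_row.bout_id,
            )
            continue
        if max_lag is not None and exit_row.frame - starts[pos] > max_lag:
            n_unattributed += 1
            continue
        outcome[idx[pos]] = 1
    scored = events.copy()
    scored["outcome"] = outcome
    if class_filter is not None:
        scored = scored.loc[scored["intensity_class"] == class_filter]
    return scored.reset_index(drop=True)


def score_dataset_exits(
    dataset: Dataset, class_filter: str | None = "high", max_lag: int | None = None
) -> pd.DataFrame:
    """:func:`score_exits` joined with male identity, status and date."""
    scored = score_exits(dataset.events, dataset.exits, class_filter, max_lag)
    return scored.merge(
        dataset.metadata.loc[:, ["bout_id", "male_id", "status", "date"]],
        on="bout_id", how="left",
    )


@dataclass
class ExitTestResult:
    """Outcome of the status contrast on exit probability."""

    method: str
    statistic: float  # owner mean proportion - subordinate mean proportion
    p_value: float
    per_male: pd.DataFrame  # male_id, status, n_elements, n_exits, proportion
    n_permutations: int | None = None
    exhaustive: bool | None = None
    chi2: float | None = None
    df: int | None = None

    def summary(self) -> str:
        lines = [f"exit-probability status contrast ({self.method})"]
        for status, group in self.per_male.groupby("status"):
            lines.append(
                f"  {status}: {len(group)} males, mean per-male exit "
                f"proportion {group['proportion'].mean():.3f}"
            )
        lines.append(f"  statistic (owner - subordinate) = {self.statistic:+.4f}")
        if self.method == "cluster_permutation":
            kind = "exhaustive" if self.exhaustive else "sampled"
            lines.append(f"  {kind} permutations: {self.n_permutations}")
        else:
            lines.append(f"  LRT chi2 = {self.chi2:.3f}, df = {self.df}")
        lines.append(f"  p = {self.p_value:.4g}")
        return "\n".join(lines)


def _per_male_proportions(outcomes: pd.DataFrame) -> pd.DataFrame:
    per_male = (
        outcomes.groupby(["male_id", "status"])["outcome"]
        .agg(n_elements="size", n_exits="sum")
        .reset_index()
    )
    per_male["proportion"] = per_male["n_exits"] / per_male["n_elements"]
    return per_male


def _status_diff(props: np.ndarray, is_owner: np.ndarray) -> float:
    return float(props[is_owner].mean() - props[~is_owner].mean())


def test_exit_status_effect(
    outcomes: pd.DataFrame,
    method: str = "cluster_permutation",
    reps: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = 50_000,
) -> ExitTestResult:
    """Test whether exit probability differs by bower-ownership status.

    ``outcomes`` must carry ``male_id``, ``status``, ``date`` and
    ``outcome`` (see :func:`score_dataset_exits`).  The default cluster
    permutation enumerates all status-label assignments when their
    number is below ``exhaustive_limit`` (two-sided p = share of
    assignments with |statistic| at least the observed |statistic|),
    falling back to ``reps`` sampled permutations with the add-one
    correction.
    """
    if outcomes.empty:
        raise EmptyGroupError("no exit outcomes to test")
    per_male = _per_male_proportions(outcomes)
    for status in ("owner", "subordinate"):
        if (per_male["status"] == status).sum() == 0:
            raise EmptyGroupError(f"no males with status {status!r}")

    props = per_male["proportion"].to_numpy()
    is_owner = (per_male["status"] == "owner").to_numpy()
    observed = _status_diff(props, is_owner)

    if method == "mixed_model":
        chi2, df, p = _glmm_lrt(outcomes)
        return ExitTestResult(
            method=method, statistic=observed, p_value=p, per_male=per_male,
            chi2=chi2, df=df,
        )
    if method != "cluster_permutation":
        raise ValueError(f"unknown method {method!r}")

    n = len(per_male)
    n_owner = int(is_owner.sum())
    if n_owner < 2 or n - n_owner < 2:
        raise InsufficientClustersError(
            "cluster permutation needs >= 2 males per status group"
        )
    total = comb(n, n_owner)
    if total <= exhaustive_limit:
        stats = np.array(
            [
                _status_diff(props, np.isin(np.arange(n), combo))
                for combo in combinations(range(n), n_owner)
            ]
        )
        p = float((np.abs(stats) >= abs(observed) - 1e-12).mean())
        return ExitTestResult(
            method=method, statistic=observed, p_value=p, per_male=per_male,
            n_permutations=total, exhaustive=True,
        )
    rng = np.random.default_rng(seed)
    stats = np.empty(reps)
    labels = is_owner.copy()
    for i in range(reps):
        rng.shuffle(labels)
        stats[i] = _status_diff(props, labels)
    p = empirical_p(abs(observed), np.abs(stats), tail="upper")
    return ExitTestResult(
        method=method, statistic=observed, p_value=p, per_male=per_male,
        n_permutations=reps, exhaustive=False,
    )


_GLMM_SCRIPT = """
suppressMessages(library(lme4))
data <- read.csv(commandArgs(trailingOnly = TRUE)[1])
data$status <- factor(data$status)
full <- glmer(outcome ~ status + (1 | male_id) + (1 | date),
              data = data, family = binomial)
null <- glmer(outcome ~ 1 + (1 | male_id) + (1 | date),
              data = data, family = binomial)
lrt <- anova(null, full)
cat(sprintf('{"chi2": %.10g, "df": %d, "p": %.10g}',
            lrt$Chisq[2], lrt$Df[2], lrt$`Pr(>Chisq)`[2]))
"""


def _glmm_lrt(outcomes: pd.DataFrame) -> tuple[float, int, float]:
    """Binomial GLMM likelihood-ratio test via R's lme4."""
    if shutil.which("Rscript") is None:
        raise RuntimeError(
            "the mixed_model method needs an R installation with lme4 on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        data_path = Path(tmp) / "outcomes.csv"
        script_path = Path(tmp) / "glmm.R"
        outcomes.loc[:, ["outcome", "status", "male_id", "date"]].to_csv(
            data_path, index=False
        )
        script_path.write_text(_GLMM_SCRIPT)
        result = subprocess.run(
            ["Rscript", "--vanilla", str(script_path), str(data_path)],
            capture_output=True, text=True,
        )
    if result.returncode != 0:
        raise RuntimeError(f"lme4 fit failed:\n{result.stderr}")
    payload = json.loads(result.stdout.strip().splitlines()[-1])
    return float(payload["chi2"]), int(payload["df"]), float(payload["p"])


def annotation_agreement(
    auto: pd.DataFrame, manual: pd.DataFrame, metrics: BodyMetrics
) -> pd.DataFrame:
    """Per-keypoint agreement between automatic and manual annotations.

    Joins the two track tables on (bout, frame, keypoint) over valid
    records and reports, per keypoint: the number of shared frames, the
    mean ± sd Euclidean error in pixels and in body-height fractions,
    and the Pearson correlation of the x and of the y coordinates.
    """
    keys = ["bout_id", "frame", "keypoint"]
    merged = auto.loc[auto["valid"], keys + ["x", "y"]].merge(
        manual.loc[manual["valid"], keys + ["x", "y"]],
        on=keys, suffixes=("_auto", "_manual"),
    )
    if merged.empty:
        raise EmptyComparisonError(
            "automatic and manual tracks share no (bout, frame, keypoint) keys"
        )
    merged["error_px"] = np.hypot(
        merged["x_auto"] - merged["x_manual"], merged["y_auto"] - merged["y_manual"]
    )
    merged["error_bh"] = merged["error_px"] / merged["bout_id"].map(metrics.means)

    rows = []
    for keypoint, group in merged.groupby("keypoint", sort=True):
        def _corr(a: pd.Series, b: pd.Series) -> float:
            if a.nunique() < 2 or b.nunique() < 2:
                return float("nan")
            return float(np.corrcoef(a, b)[0, 1])

        rows.append(
            {
                "keypoint": keypoint,
                "n_frames": len(group),
                "mean_error_px": float(group["error_px"].mean()),
                "sd_error_px": float(group["error_px"].std(ddof=1)),
                "mean_error_bh": float(group["error_bh"].mean()),
                "sd_error_bh": float(group["error_bh"].std(ddof=1)),
                "r_x": _corr(group["x_auto"], group["x_manual"]),
                "r_y": _corr(group["y_auto"], group["y_manual"]),
            }
        )
    return pd.DataFrame(rows)
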