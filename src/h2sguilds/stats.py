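"""Two-group comparisons: the two-sided Wilcoxon rank-sum test.

All cohort and guild contrasts reduce to an unpaired two-sided
Mann-Whitney/Wilcoxon test on per-sample guild abundance vectors. The
test statistic is reported both as the Mann-Whitney U of group 1 and as
the rank-sum W = U + n1(n1+1)/2 (the form quoted in the field, e.g.
"W = 123,784"). The exact null distribution is enumerated for small
tie-free problems (n1 + n2 <= 12); larger or tied problems use the
normal approximation with midranks, tie-corrected variance and a
continuity correction — the same convention as R's ``wilcox.test``.

p-values below 2.2e-16 are printed as the floor string ``"< 2.2e-16"``
while the raw float is retained on the result object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .abundance import GuildAbundance
from .errors import ConsistencyError

logger = logging.getLogger(__name__)

#: Smallest p-value printed numerically; below it reports show "< 2.2e-16".
P_FLOOR = 2.2e-16

#: Largest pooled size for which the exact null distribution is enumerated.
EXACT_MAX_POOLED = 12


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of a two-sided Wilcoxon rank-sum test.

    ``u_statistic`` is the Mann-Whitney U of the first group;
    ``w_statistic`` is the corresponding rank sum, W = U + n1(n1+1)/2.
    """

    w_statistic: float
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: Literal["exact", "normal_approx"]

    def formatted_p(self) -> str:
        """p for printing, floored at 2.2e-16 as is conventional."""
        if self.p_value < P_FLOOR:
            return "< 2.2e-16"
        return f"{self.p_value:.3g}"


def rank_sum_test(
    x: Sequence[float], y: Sequence[float]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of x versus y.

    Midranks are used for ties. The exact distribution is enumerated when
    n1 + n2 <= 12 and the pooled data are tie-free; otherwise the normal
    approximation with tie-corrected variance and continuity correction is
    used. Two identical constant groups yield p = 1 (with a logged
    warning) since the data carry no ordering information.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = int(xa.size), int(ya.size)

    pooled = np.concatenate([xa, ya])
    if np.all(pooled == pooled[0]):
        logger.warning("rank_sum_test: all pooled values identical; p = 1")
        u = n1 * n2 / 2.0
        return RankSumResult(
            w_statistic=u + n1 * (n1 + 1) / 2.0,
            u_statistic=u, p_value=1.0, n1=n1, n2=n2, method="normal_approx",
        )

    no_ties = np.unique(pooled).size == pooled.size
    if n1 + n2 <= EXACT_MAX_POOLED and no_ties:
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
        method: Literal["exact", "normal_approx"] = "exact"
    else:
        res = sps.mannwhitneyu(
            xa, ya, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        method = "normal_approx"
    u = float(res.statistic)
    return RankSumResult(
        w_statistic=u + n1 * (n1 + 1) / 2.0,
        u_statistic=u,
        p_value=min(float(res.pvalue), 1.0),
        n1=n1, n2=n2, method=method,
    )


def compare_guild_between_cohorts(
    ga: GuildAbundance,
    sample_meta: Mapping[str, Mapping[str, str]],
    cohort_a: str,
    cohort_b: str,
) -> RankSumResult:
    """Rank-sum test of one guild's abundance between two cohorts.

    Group 1 collects the samples labeled *cohort_a* in *sample_meta*,
    group 2 those labeled *cohort_b*. Unknown cohort labels raise a
    :class:`KeyError` listing the labels present.
    """
    by_cohort: dict[str, list[float]] = {}
    for sample, value in ga.per_sample.items():
        cohort = sample_meta.get(sample, {}).get("cohort")
        if cohort is not None:
            by_cohort.setdefault(cohort, []).append(value)
    for label in (cohort_a, cohort_b):
        if label not in by_cohort:
            raise KeyError(
                f"cohort {label!r} has no samples; cohorts present: "
                f"{sorted(by_cohort)}"
            )
    return rank_sum_test(by_cohort[cohort_a], by_cohort[cohort_b])


def compare_guilds_within_cohort(
    ga1: GuildAbundance,
    ga2: GuildAbundance,
    samples: Optional[Sequence[str]] = None,
    paired: bool = False,
) -> RankSumResult:
    """Rank-sum test between two guilds' abundances over the same samples.

    Both guilds must be defined on every requested sample. The default is
    the unpaired two-sided rank-sum test (the convention behind the
    guild-versus-guild contrasts); ``paired=True`` switches to the
    Wilcoxon signed-rank test as a sensitivity analysis.
    """
    keys = list(ga1.per_sample) if samples is None else list(samples)
    missing1 = [s for s in keys if s not in ga1.per_sample]
    missing2 = [s for s in keys if s not in ga2.per_sample]
    if missing1 or missing2:
        raise ConsistencyError(
            f"guild abundances not defined on the same samples; missing "
            f"{(missing1 + missing2)[:5]}"
        )
    v1 = ga1.vector(keys)
    v2 = ga2.vector(keys)
    if paired:
        d = v1 - v2
        if np.all(d == 0):
            return RankSumResult(
                w_statistic=0.0, u_statistic=0.0, p_value=1.0,
                n1=len(keys), n2=len(keys), method="normal_approx",
            )
        res = sps.wilcoxon(v1, v2, alternative="two-sided")
        return RankSumResult(
            w_statistic=float(res.statistic), u_statistic=float("nan"),
            p_value=float(res.pvalue), n1=len(keys), n2=len(keys),
            method="normal_approx",
        )
    return rank_sum_test(v1, v2)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for batch comparisons
    (opt-in; single contrasts are reported raw)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float))


def write_comparison_table(
    rows: Iterable[Mapping[str, object]], dest: Union[str, Path]
) -> None:
    """Write comparison results as TSV.

    Each row mapping must provide guild, cohort_a, cohort_b and a
    :class:`RankSumResult` under key ``result``.
    """
    lines = ["guild\tcohort_a\tcohort_b\tn1\tn2\tW\tU\tp\tp_printed\tmethod"]
    for row in rows:
        r: RankSumResult = row["result"]  # type: ignore[assignment]
        lines.append(
            f"{row['guild']}\t{row['cohort_a']}\t{row['cohort_b']}\t"
            f"{r.n1}\t{r.n2}\t{r.w_statistic:.6g}\t{r.u_statistic:.6g}\t"
            f"{r.p_value:.6g}\t{r.formatted_p()}\t{r.method}"
        )
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")
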