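"""Group comparisons for the monitored-point samples, and report rendering.

The comparison scheme mirrors the factorial design: within surgery x bone
quality across loads, within surgery x load across bone qualities, and within
bone quality x load across surgeries. Each grouping is tested with one-way
ANOVA when every group passes a Shapiro-Wilk normality check, otherwise with
Kruskal-Wallis; pairwise post-hoc comparisons are Bonferroni-adjusted.

The Kruskal-Wallis statistic uses the standard tie correction. For small
pooled samples an exact permutation p-value is computed by enumerating all
distinct assignments of the pooled observations to the groups; otherwise the
chi-squared approximation is used.

Caveat documented in every report: the 16 monitored points of one
deterministic solution are pseudo-replicates, not independent samples, so
these tests describe the spatial fields, not sampling uncertainty.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

__all__ = [
    "DegenerateDataError",
    "ComparisonResult",
    "choose_test",
    "kruskal_statistic",
    "kruskal_test",
    "compare_groups",
    "type_one_error_rate",
    "render_tables",
]

#: Above this pooled sample size the exact permutation null is not enumerated.
_EXACT_N_LIMIT = 13


class DegenerateDataError(ValueError):
    """Groups carry no usable variation (e.g. identical constants)."""


@dataclass
class ComparisonResult:
    """Omnibus test plus Bonferroni-adjusted pairwise p-values."""

    label: str
    test: str  # "anova" | "kruskal"
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_raw: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_groups(samples) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 3 for g in groups):
        raise ValueError("every group needs at least 3 values")
    return groups


def choose_test(samples, alpha: float = 0.05) -> str:
    """'anova' if every group passes Shapiro-Wilk at alpha, else 'kruskal'."""
    groups = _as_groups(samples)
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise DegenerateDataError("all groups are one identical constant")
    for g in groups:
        if np.ptp(g) == 0:  # constant group: Shapiro undefined, clearly non-normal
            return "kruskal"
        if sps.shapiro(g).pvalue <= alpha:
            return "kruskal"
    return "anova"


def kruskal_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction; 0 when all values are tied."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts ** 3 - counts))
    denom = 1.0 - ties / (n ** 3 - n)
    if denom <= 0:
        return 0.0  # every observation identical
    return h / denom


def _exact_permutation_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact p-value: enumerate distinct assignments of pooled values to groups."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    n = pooled.size
    n_total = n * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts ** 3 - counts))
    denom = 1.0 - ties / (n ** 3 - n)

    def h_from_sums(sq_over_n: float) -> float:
        h = 12.0 / n_total * sq_over_n - 3.0 * (n + 1)
        return h / denom if denom > 0 else 0.0

    count = 0
    total = 0
    idx_all = tuple(range(n))

    def rec(remaining: tuple[int, ...], gi: int, acc: float) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            r = sum(ranks[i] for i in remaining)
            h = h_from_sums(acc + r * r / sizes[-1])
            total += 1
            if h >= h_obs - 1e-9:
                count += 1
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            r = sum(ranks[i] for i in comb)
            rest = tuple(i for i in remaining if i not in set(comb))
            rec(rest, gi + 1, acc + r * r / sizes[gi])

    rec(idx_all, 0, 0.0)
    return count / total


def kruskal_test(samples, method: str = "auto") -> tuple[float, float]:
    """Kruskal-Wallis omnibus test; returns (H, p).

    method: 'exact' (enumerated permutation null), 'asymptotic' (chi-squared),
    or 'auto' (exact when the pooled sample size is small enough).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in samples]
    h = kruskal_statistic(groups)
    n = sum(g.size for g in groups)
    if method == "auto":
        method = "exact" if n <= _EXACT_N_LIMIT else "asymptotic"
    if method == "exact":
        if n > 2 * _EXACT_N_LIMIT:
            raise ValueError("exact enumeration requested for a sample too large")
        return h, _exact_permutation_p(groups, h)
    if method == "asymptotic":
        if h == 0.0:
            return 0.0, 1.0
        return h, float(sps.chi2.sf(h, df=len(groups) - 1))
    raise ValueError(f"unknown method {method!r}")


def compare_groups(samples, test: str, labels: list[str] | None = None,
                   alpha: float = 0.05, method: str = "auto",
                   group_label: str = "") -> ComparisonResult:
    """Omnibus test plus Bonferroni-adjusted pairwise post-hoc comparisons."""
    groups = _as_groups(samples)
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    if test == "anova":
        res = sps.f_oneway(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal":
        stat, p = kruskal_test(groups, method=method)
    else:
        raise ValueError(f"unknown test {test!r}")

    pairs = list(itertools.combinations(range(len(groups)), 2))
    raw: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        key = (labels[a], labels[b])
        if test == "anova":
            raw[key] = float(sps.ttest_ind(groups[a], groups[b]).pvalue)
        else:
            _, raw[key] = kruskal_test([groups[a], groups[b]], method=method)
    adj = {k: min(1.0, v * len(pairs)) for k, v in raw.items()}
    return ComparisonResult(label=group_label, test=test, statistic=stat,
                            p_value=p, pairwise=adj, pairwise_raw=raw, alpha=alpha)


def type_one_error_rate(n_groups: int = 3, n: int = 16, reps: int = 1000,
                        seed: int = 20230801, alpha: float = 0.05) -> float:
    """Monte-Carlo omnibus rejection rate under the null (all groups identical).

    Each replicate draws ``n_groups`` standard-normal samples of size ``n``,
    routes them through :func:`choose_test` and :func:`compare_groups`, and
    counts omnibus rejections at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        groups = [rng.standard_normal(n) for _ in range(n_groups)]
        test = choose_test(groups, alpha=alpha)
        res = compare_groups(groups, test, alpha=alpha, method="asymptotic")
        rejections += res.p_value < alpha
    return rejections / reps


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

_CHANNELS = {"stress": "Von Mises stress (MPa)", "displacement": "Displacement (um)"}

_PSEUDOREP_FOOTER = (
    "NOTE: samples are the 16 monitored points of one deterministic solution "
    "per cell - pseudo-replicates, not independent measurements. The tests "
    "describe spatial variation across the monitored surface, and absolute "
    "magnitudes are geometry-specific; only qualitative orderings carry over "
    "to other geometries."
)


def _comparison_rows(grid_samples, index_keys, compare_key, channel):
    """Shared driver for the three comparison layouts."""
    rows = []
    choices = []
    index = sorted({tuple(k[i] for i in index_keys) for k in grid_samples})
    for fixed in index:
        members = sorted(
            (k for k in grid_samples if tuple(k[i] for i in index_keys) == fixed),
            key=lambda k: k[compare_key],
        )
        labels = [str(k[compare_key]) for k in members]
        groups = [grid_samples[k] for k in members]
        try:
            test = choose_test(groups)
        except DegenerateDataError:
            continue
        res = compare_groups(groups, test, labels=labels,
                             group_label=" / ".join(map(str, fixed)))
        choices.append((channel, res.label, test))
        for (a, b), p_adj in res.pairwise.items():
            rows.append(
                {
                    "channel": channel,
                    "group": res.label,
                    "comparison": f"{a}:{b}",
                    "test": test,
                    "omnibus_statistic": res.statistic,
                    "omnibus_p": res.p_value,
                    "pairwise_p_bonferroni": p_adj,
                    "significant": p_adj < res.alpha,
                }
            )
    return rows, choices


def render_tables(grid, outdir) -> dict[str, Path]:
    """Write the three comparison layouts plus a markdown report.

    ``grid`` is an :class:`~cervifem.experiment.GridSummary`. Produces
    ``table3_analog.csv`` (across loads), ``table4_analog.csv`` (across bone
    qualities), ``table5_analog.csv`` (across surgeries), and ``report.md``.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layouts = {
        # (index key positions in (surgery, bone, load), compared key position)
        "table3_analog": ((0, 1), 2),  # within surgery x quality, across loads
        "table4_analog": ((0, 2), 1),  # within surgery x load, across qualities
        "table5_analog": ((1, 2), 0),  # within quality x load, across surgeries
    }
    paths: dict[str, Path] = {}
    paths["grid_summary"] = outdir / "grid_summary.csv"
    grid.table.to_csv(paths["grid_summary"], index=False)
    all_choices = []
    frames = {}
    for name, (index_keys, compare_key) in layouts.items():
        rows = []
        for channel in _CHANNELS:
            r, choices = _comparison_rows(grid.samples(channel), index_keys,
                                          compare_key, channel)
            rows.extend(r)
            all_choices.extend((name, *c) for c in choices)
        df = pd.DataFrame(rows)
        frames[name] = df
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)

    report = outdir / "report.md"
    with report.open("w") as fh:
        fh.write("# Factorial comparison report\n\n## Cell summaries\n\n")
        fh.write(grid.table.to_markdown(index=False))
        fh.write("\n\n")
        for name, df in frames.items():
            fh.write(f"## {name}\n\n")
            fh.write(df.to_markdown(index=False) if len(df) else "(no comparisons)")
            fh.write("\n\n")
        fh.write("## Test choices\n\n")
        for name, channel, label, test in all_choices:
            fh.write(f"- {name} / {channel} / {label}: {test}\n")
        fh.write(f"\n{_PSEUDOREP_FOOTER}\n")
    paths["report"] = report
    return paths
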