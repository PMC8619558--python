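"""Cross-modality agreement statistics for paired ROI means.

Given pairs (MDCT mean, DE-CBCT mean) per ROI, this module produces the
three analyses used to judge voxel-value agreement:

* identity-line deviation bands: the vertical offset of each point from the
  y = x line, as a percentage of the reference (MDCT) value, binned into
  ``|dev| <= 10``, ``10 < |dev| <= 15``, ``15 < |dev| <= 20`` and
  ``|dev| > 20`` percent (bands closed at their outer edge);
* a Shapiro-Wilk normality gate (Royston's AS R94, via scipy) on the
  percent differences, passing when p > 0.01;
* a Bland-Altman analysis of percent differences
  ``100 * (MDCT - DECBCT) / average``: bias (mean difference), limits of
  agreement bias +/- z*SD (z = 1.96), the confidence interval of the bias
  (t-based) and of the limits (full width ``2*z*s*sqrt(3/n)``), and counts
  of points outside the limits and outside the outer CI edges.

Reports carry full-precision values alongside display rounding (one decimal
for percentages of counts, two decimals for Bland-Altman quantities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateFitError
from .roi import MeasurementPair

__all__ = [
    "BAND_EDGES",
    "GroupBands",
    "BandReport",
    "BAResult",
    "GroupAnalysis",
    "AgreementReport",
    "deviation_percent",
    "percent_difference",
    "band_report",
    "shapiro_wilk",
    "bland_altman",
    "count_outside",
    "agreement_report",
    "plot_identity_scatter",
    "plot_bland_altman",
]

BAND_EDGES = (10.0, 15.0, 20.0)
SW_ALPHA = 0.01


def deviation_percent(pair: MeasurementPair, reference: str = "mdct") -> float:
    """Vertical offset from the identity line as % of the reference value.

    ``reference="mdct"`` (default) measures relative to the x-axis (MDCT)
    value; ``reference="average"`` relative to the pair mean.
    """
    if reference == "mdct":
        ref = pair.mean_mdct
    elif reference == "average":
        ref = (pair.mean_mdct + pair.mean_decbct) / 2.0
    else:
        raise ValueError(f"unknown deviation reference {reference!r}")
    if ref == 0:
        raise ZeroDivisionError(f"pair {pair.label!r}: zero reference mean")
    return 100.0 * (pair.mean_decbct - pair.mean_mdct) / ref


def percent_difference(pair: MeasurementPair) -> float:
    """Bland-Altman percent difference 100*(MDCT - DECBCT)/average."""
    avg = (pair.mean_mdct + pair.mean_decbct) / 2.0
    if avg <= 0:
        raise DegenerateFitError(
            f"pair {pair.label!r}: non-positive average ({avg}); pair must be excluded"
        )
    return 100.0 * (pair.mean_mdct - pair.mean_decbct) / avg


@dataclass(frozen=True)
class GroupBands:
    """Deviation-band counts for one group: (<=10, 10-15, 15-20, >20)."""

    n: int
    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n:
            raise ValueError(f"band counts {self.counts} do not sum to n={self.n}")

    @property
    def percentages(self) -> tuple[float, ...]:
        return tuple(100.0 * c / self.n for c in self.counts)

    @property
    def percentages_rounded(self) -> tuple[float, ...]:
        return tuple(float(np.round(p, 1)) for p in self.percentages)

    @property
    def within_15_percent(self) -> float:
        """Percentage of points with |deviation| <= 15."""
        return 100.0 * (self.counts[0] + self.counts[1]) / self.n


@dataclass
class BandReport:
    groups: dict[str, GroupBands]

    @classmethod
    def from_deviations(cls, devs_by_group: dict[str, np.ndarray]) -> "BandReport":
        groups = {}
        for g, devs in devs_by_group.items():
            devs = np.abs(np.asarray(devs, dtype=float))
            if devs.size == 0:
                raise DegenerateFitError(f"group {g!r} has no deviations")
            c0 = int((devs <= BAND_EDGES[0]).sum())
            c1 = int(((devs > BAND_EDGES[0]) & (devs <= BAND_EDGES[1])).sum())
            c2 = int(((devs > BAND_EDGES[1]) & (devs <= BAND_EDGES[2])).sum())
            c3 = int((devs > BAND_EDGES[2]).sum())
            groups[g] = GroupBands(n=devs.size, counts=(c0, c1, c2, c3))
        return cls(groups=groups)

    @classmethod
    def from_counts(cls, counts_by_group: dict[str, tuple[int, int, int, int]]) -> "BandReport":
        """Build the report layer directly from band counts (published tables)."""
        return cls(
            groups={
                g: GroupBands(n=sum(c), counts=tuple(int(x) for x in c))
                for g, c in counts_by_group.items()
            }
        )

    def to_dict(self) -> dict:
        return {
            g: {
                "n": b.n,
                "counts": list(b.counts),
                "percentages": list(b.percentages),
                "percentages_rounded": list(b.percentages_rounded),
            }
            for g, b in self.groups.items()
        }


def band_report(pairs: list[MeasurementPair], reference: str = "mdct") -> BandReport:
    """Identity-line deviation bands per group and combined."""
    if not pairs:
        raise DegenerateFitError("band_report: no measurement pairs")
    devs_by_group: dict[str, list[float]] = {}
    for p in pairs:
        devs_by_group.setdefault(p.group, []).append(deviation_percent(p, reference))
    devs_by_group["combined"] = [deviation_percent(p, reference) for p in pairs]
    return BandReport.from_deviations({g: np.asarray(v) for g, v in devs_by_group.items()})


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's AS R94 approximation)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise DegenerateFitError("Shapiro-Wilk undefined for constant input")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BAResult:
    """Bland-Altman summary of percent differences."""

    n: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    gap: float  # z * sd: distance from bias to each agreement limit
    ci_bias_halfwidth: float
    ci_loa_fullwidth: float
    z: float = 1.96
    n_outside_loa: int | None = None
    n_outside_outer_ci: int | None = None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "gap": self.gap,
            "ci_bias_halfwidth": self.ci_bias_halfwidth,
            "ci_loa_fullwidth": self.ci_loa_fullwidth,
            "z": self.z,
            "n_outside_loa": self.n_outside_loa,
            "n_outside_outer_ci": self.n_outside_outer_ci,
        }
        d["display"] = {
            k: float(np.round(d[k], 2))
            for k in ("bias", "sd", "loa_low", "loa_high", "gap", "ci_bias_halfwidth", "ci_loa_fullwidth")
        }
        return d


def bland_altman(diffs, z: float = 1.96, loa_ci: str = "z") -> BAResult:
    """Bias, limits of agreement, and their confidence intervals.

    ``gap = z*s`` separates the bias from each agreement limit. The CI of the
    bias has half-width ``t_{0.975, n-1} * s / sqrt(n)``; the CI of each
    agreement limit is reported as the full width ``2*z*s*sqrt(3/n)``
    (``loa_ci="t"`` substitutes the t quantile for z in that width).
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError(f"Bland-Altman requires n >= 3, got {n}")
    bias = float(d.mean())
    s = float(d.std(ddof=1))
    gap = z * s
    tq = float(sps.t.ppf(0.975, n - 1))
    mult = tq if loa_ci == "t" else z
    return BAResult(
        n=n,
        bias=bias,
        sd=s,
        loa_low=bias - gap,
        loa_high=bias + gap,
        gap=gap,
        ci_bias_halfwidth=tq * s / np.sqrt(n),
        ci_loa_fullwidth=2.0 * mult * s * np.sqrt(3.0 / n),
        z=z,
    )


def count_outside(diffs, ba: BAResult) -> tuple[int, int]:
    """Points beyond the agreement limits, and beyond the outer CI edges."""
    d = np.asarray(diffs, dtype=float)
    out_loa = int(((d < ba.loa_low) | (d > ba.loa_high)).sum())
    half = ba.ci_loa_fullwidth / 2.0
    out_ci = int(((d < ba.loa_low - half) | (d > ba.loa_high + half)).sum())
    return out_loa, out_ci


@dataclass
class GroupAnalysis:
    group: str
    n: int
    deviations: np.ndarray
    diffs: np.ndarray
    bands: GroupBands
    sw: tuple[float, float] | None  # (W, p); None when degenerate (constant diffs)
    sw_passed: bool | None
    ba: BAResult | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "shapiro_wilk": None
            if self.sw is None
            else {"W": self.sw[0], "p": self.sw[1], "passed": self.sw_passed},
            "bands": {
                "counts": list(self.bands.counts),
                "percentages": list(self.bands.percentages),
                "percentages_rounded": list(self.bands.percentages_rounded),
            },
            "bland_altman": None if self.ba is None else self.ba.to_dict(),
        }


@dataclass
class AgreementReport:
    groups: dict[str, GroupAnalysis]
    excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "groups": {g: a.to_dict() for g, a in self.groups.items()},
            "excluded": list(self.excluded),
        }


def agreement_report(
    pairs: list[MeasurementPair],
    reference: str = "mdct",
    z: float = 1.96,
    loa_ci: str = "z",
) -> AgreementReport:
    """Full per-group and combined analysis.

    Groups failing the normality gate are flagged but fully analyzed. Pairs
    with non-positive averages (percent difference undefined) are recorded
    as excluded, never silently dropped.
    """
    if not pairs:
        raise DegenerateFitError("agreement_report: no measurement pairs")
    usable: list[MeasurementPair] = []
    excluded: list[tuple[str, str]] = []
    for p in pairs:
        try:
            percent_difference(p)
        except DegenerateFitError as exc:
            excluded.append((p.label, str(exc)))
            continue
        usable.append(p)
    if not usable:
        raise DegenerateFitError("agreement_report: all pairs excluded")

    by_group: dict[str, list[MeasurementPair]] = {}
    for p in usable:
        by_group.setdefault(p.group, []).append(p)
    order = list(by_group.keys())
    if len(order) > 1 or "combined" not in order:
        by_group["combined"] = list(usable)

    groups: dict[str, GroupAnalysis] = {}
    for g, members in by_group.items():
        devs = np.array([deviation_percent(p, reference) for p in members])
        diffs = np.array([percent_difference(p) for p in members])
        bands = BandReport.from_deviations({g: devs}).groups[g]
        sw = sw_passed = None
        if diffs.size >= 3 and np.ptp(diffs) > 0:
            sw = shapiro_wilk(diffs)
            sw_passed = sw[1] > SW_ALPHA
        ba = None
        if diffs.size >= 3:
            ba = bland_altman(diffs, z=z, loa_ci=loa_ci)
            ba.n_outside_loa, ba.n_outside_outer_ci = count_outside(diffs, ba)
        groups[g] = GroupAnalysis(
            group=g, n=len(members), deviations=devs, diffs=diffs,
            bands=bands, sw=sw, sw_passed=sw_passed, ba=ba,
        )
    return AgreementReport(groups=groups, excluded=excluded)


# ---------------------------------------------------------------------------
# optional static plots (identity scatter with bands; Bland-Altman)
# ---------------------------------------------------------------------------


def plot_identity_scatter(pairs: list[MeasurementPair], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.mean_mdct for p in pairs])
    y = np.array([p.mean_decbct for p in pairs])
    lo, hi = min(x.min(), y.min()), max(x.max(), y.max())
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    xs = np.linspace(lo - pad, hi + pad, 2)
    fig, ax = plt.subplots(figsize=(5, 5))
    for g in sorted({p.group for p in pairs}):
        sel = [p.group == g for p in pairs]
        ax.scatter(x[sel], y[sel], s=14, label=g)
    ax.plot(xs, xs, "k-", lw=1, label="identity")
    for frac, style in zip(BAND_EDGES, ("--", ":", (0, (1, 3)))):
        ax.plot(xs, xs * (1 + frac / 100.0), color="gray", ls=style, lw=0.8)
        ax.plot(xs, xs * (1 - frac / 100.0), color="gray", ls=style, lw=0.8)
    ax.set_xlabel("MDCT ROI mean (HU)")
    ax.set_ylabel("DE-CBCT ROI mean (HU)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(pairs: list[MeasurementPair], ba: BAResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = np.array([(p.mean_mdct + p.mean_decbct) / 2.0 for p in pairs])
    diffs = np.array([percent_difference(p) for p in pairs])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=14)
    half = ba.ci_loa_fullwidth / 2.0
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    for y0 in (ba.loa_low, ba.loa_high):
        ax.axhspan(y0 - half, y0 + half, color="tab:blue", alpha=0.15)
    ax.axhspan(ba.bias - ba.ci_bias_halfwidth, ba.bias + ba.ci_bias_halfwidth,
               color="tab:orange", alpha=0.15)
    ax.set_xlabel("pair mean (HU)")
    ax.set_ylabel("difference (MDCT - DE-CBCT)/average (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
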