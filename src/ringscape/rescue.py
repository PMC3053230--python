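"""Quantification of transgenic-rescue fertility assays.

In a rescue assay a transgene carrying a candidate mutation is introduced
into a sterile null-mutant background and protein function is read out as
brood size (total live progeny per hermaphrodite).  Several independently
derived transgenic lines are scored per construct because extrachromosomal
arrays vary strongly from line to line.  The quantities of interest are:

* per-line summaries (mean brood +/- SEM over worms),
* a genotype-level rescue fraction — the ratio of the genotype's grand
  mean brood to that of lines carrying a wild-type transgene,
* a coarse classification (null-like / partial / full rescue), and
* a compensation test for residue pairs where one residue can stand in
  for the loss of another: the single mutants rescue well, the double
  mutant collapses to the null-like level.

The module exposes both a functional surface (:func:`line_summary`,
:func:`genotype_rescue`, ...) and a model-style wrapper
(:class:`RescueModel` -> :class:`RescueResults`) for dataframe input.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Numeric stand-in for table entries printed as "<1" (interval (0, 1)).
LT1_VALUE = 0.5


class RescueDataError(ValueError):
    """Invalid brood-count input."""


@dataclass(frozen=True)
class LineSummary:
    mean: float
    sem: float
    n: int
    flags: tuple[str, ...] = ()

    def progeny_str(self) -> str:
        """Render the mean the way assay tables print it ("<1" below one)."""
        if 0 < self.mean < 1:
            return "<1"
        return f"{self.mean:.0f} ± {self.sem:.0f}"


def line_summary(counts: Sequence[int]) -> LineSummary:
    """Mean, SEM (n-1 sample SD over sqrt n) and n for one line's broods."""
    counts = list(counts)
    if not counts:
        raise RescueDataError("empty brood-count list")
    if any(c < 0 for c in counts):
        raise RescueDataError("negative brood count")
    arr = np.asarray(counts, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    if n == 1:
        return LineSummary(mean, 0.0, 1, flags=("sem-undefined-n1",))
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    return LineSummary(mean, sem, n)


@dataclass(frozen=True)
class RescueLine:
    """One transgenic line: raw per-worm broods and/or a printed summary."""

    transgene_id: str
    genotype_label: str
    mean: float
    sem: float
    n: int
    counts: tuple[int, ...] | None = None
    flags: tuple[str, ...] = ()
    control_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise RescueDataError(f"line {self.transgene_id}: n must be >= 1")
        if self.mean < 0 or self.sem < 0:
            raise RescueDataError(f"line {self.transgene_id}: negative summary")
        if self.counts is not None:
            s = line_summary(self.counts)
            if (
                abs(s.mean - self.mean) > 1e-9
                or abs(s.sem - self.sem) > 1e-9
                or s.n != self.n
            ):
                raise RescueDataError(
                    f"line {self.transgene_id}: summary does not match counts"
                )

    @classmethod
    def from_counts(
        cls, transgene_id, genotype_label, counts, control_counts=None
    ) -> "RescueLine":
        s = line_summary(counts)
        return cls(
            transgene_id,
            genotype_label,
            s.mean,
            s.sem,
            s.n,
            counts=tuple(int(c) for c in counts),
            flags=s.flags,
            control_counts=None if control_counts is None else tuple(control_counts),
        )

    @classmethod
    def from_summary(
        cls, transgene_id, genotype_label, mean, sem, n, flags=()
    ) -> "RescueLine":
        return cls(transgene_id, genotype_label, float(mean), float(sem), int(n), flags=tuple(flags))


@dataclass(frozen=True)
class RescueThresholds:
    """Classification cut points on the rescue fraction.

    Below ``null_like_max`` a genotype is null-like; above ``full_min`` it
    is full rescue; both boundaries themselves classify upward as partial.
    """

    null_like_max: float = 0.10
    full_min: float = 0.80


def classify_rescue(fraction: float, thresholds: RescueThresholds | None = None) -> str:
    if fraction < 0:
        raise RescueDataError("negative rescue fraction")
    t = thresholds or RescueThresholds()
    if fraction < t.null_like_max:
        return "null-like"
    if fraction <= t.full_min:
        return "partial"
    return "full"


@dataclass(frozen=True)
class GenotypeSummary:
    genotype_label: str
    line_means: tuple[float, ...]
    grand_mean: float
    rescue_fraction: float
    classification: str

    @property
    def rescue_percent(self) -> float:
        return 100.0 * self.rescue_fraction


def _grand_mean(lines: Sequence[RescueLine], weighting: str) -> float:
    means = np.array([ln.mean for ln in lines], dtype=float)
    if weighting == "unweighted":
        return float(means.mean())
    if weighting == "n-weighted":
        ns = np.array([ln.n for ln in lines], dtype=float)
        return float((means * ns).sum() / ns.sum())
    raise ValueError(f"unknown weighting {weighting!r}")


def genotype_rescue(
    lines: Sequence[RescueLine],
    reference: Sequence[RescueLine],
    weighting: str = "unweighted",
    thresholds: RescueThresholds | None = None,
) -> GenotypeSummary:
    """Rescue fraction of a genotype relative to the wild-type transgene.

    The grand mean is the mean of line means (unweighted by default:
    independently derived lines are the replication unit, which controls
    for array-to-array expression variation); ``n-weighted`` pools worms.
    """
    if not lines or not reference:
        raise RescueDataError("both genotype and reference lines required")
    ref_mean = _grand_mean(reference, weighting)
    if ref_mean <= 0:
        raise RescueDataError("reference grand mean must be positive")
    gm = _grand_mean(lines, weighting)
    frac = gm / ref_mean
    label = lines[0].genotype_label
    return GenotypeSummary(
        genotype_label=label,
        line_means=tuple(ln.mean for ln in lines),
        grand_mean=gm,
        rescue_fraction=frac,
        classification=classify_rescue(frac, thresholds),
    )


@dataclass(frozen=True)
class CompensationThresholds:
    """Tolerances for the single/double-mutant compensation verdict."""

    better_than_double_margin: float = 0.05
    product_rel_tol: float = 0.25
    product_abs_tol: float = 0.02


@dataclass(frozen=True)
class CompensationResult:
    single_a: float
    single_b: float
    double: float
    verdict: str  # compensatory | independent | inconclusive


def compensation_test(
    single_a: GenotypeSummary,
    single_b: GenotypeSummary,
    double: GenotypeSummary,
    thresholds: CompensationThresholds | None = None,
    rescue_thresholds: RescueThresholds | None = None,
) -> CompensationResult:
    """Classify the joint behaviour of two single mutants and their double.

    *compensatory*: residue A alone is dispensable (full rescue), residue B
    alone retains function beyond the double (partial, or clearly better
    than the double), yet the double mutant is null-like — the signature
    that A substitutes for B when B is lost.

    *independent*: the double's fraction matches the product of the
    singles' fractions (multiplicative null model of unrelated defects).

    Anything else — including two null-like singles, which carry no signal
    about interaction — is *inconclusive*.
    """
    t = thresholds or CompensationThresholds()
    fa, fb, fd = (
        single_a.rescue_fraction,
        single_b.rescue_fraction,
        double.rescue_fraction,
    )
    cls = lambda s: classify_rescue(s, rescue_thresholds)
    a_cls, b_cls, d_cls = cls(fa), cls(fb), cls(fd)
    if a_cls == "null-like" and b_cls == "null-like":
        verdict = "inconclusive"
    elif (
        a_cls == "full"
        and d_cls == "null-like"
        and (b_cls == "partial" or fb > fd + t.better_than_double_margin)
    ):
        verdict = "compensatory"
    elif abs(fd - fa * fb) <= max(t.product_rel_tol * fa * fb, t.product_abs_tol):
        verdict = "independent"
    else:
        verdict = "inconclusive"
    return CompensationResult(fa, fb, fd, verdict)


def recombinant_filter(
    lines: Sequence[RescueLine],
) -> tuple[list[RescueLine], list[dict]]:
    """Drop lines whose non-transgenic control siblings produced progeny.

    In these assays the untransformed null homozygote is completely
    sterile, so any progeny from control siblings flags a recombinant
    chromosome and the whole line is excluded.  Lines without control
    broods are retained with a logged warning.
    """
    kept, log = [], []
    for ln in lines:
        if ln.control_counts is None:
            log.append(
                {
                    "transgene_id": ln.transgene_id,
                    "action": "retained",
                    "reason": "no control broods recorded",
                }
            )
            kept.append(ln)
        elif any(c > 0 for c in ln.control_counts):
            log.append(
                {
                    "transgene_id": ln.transgene_id,
                    "action": "excluded",
                    "reason": f"control sibling progeny {max(ln.control_counts)} > 0 "
                    "(recombination indicator)",
                }
            )
        else:
            log.append(
                {"transgene_id": ln.transgene_id, "action": "retained", "reason": "controls sterile"}
            )
            kept.append(ln)
    return kept, log


def bootstrap_ci(
    lines: Sequence[RescueLine],
    reference: Sequence[RescueLine],
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    weighting: str = "unweighted",
) -> tuple[float, float]:
    """Percentile bootstrap interval for the rescue fraction.

    Resamples lines (the replication unit) with replacement in both arms.
    Purely descriptive; with very few lines the interval is anti-
    conservative and a single line makes it degenerate (warned).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if len(lines) == 1 or len(reference) == 1:
        warnings.warn("single line in an arm: bootstrap interval is degenerate")
    rng = np.random.default_rng(seed)
    mut = np.array([ln.mean for ln in lines], dtype=float)
    ref = np.array([ln.mean for ln in reference], dtype=float)
    mut_n = np.array([ln.n for ln in lines], dtype=float)
    ref_n = np.array([ln.n for ln in reference], dtype=float)

    def arm_mean(means, ns, idx):
        if weighting == "n-weighted":
            return (means[idx] * ns[idx]).sum() / ns[idx].sum()
        return means[idx].mean()

    fracs = np.empty(B)
    for b in range(B):
        mi = rng.integers(0, len(mut), len(mut))
        ri = rng.integers(0, len(ref), len(ref))
        denom = arm_mean(ref, ref_n, ri)
        fracs[b] = arm_mean(mut, mut_n, mi) / denom if denom > 0 else np.nan
    fracs = fracs[np.isfinite(fracs)]
    lo, hi = np.percentile(fracs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Dataframe-facing model wrapper
# ---------------------------------------------------------------------------


def lines_from_dataframe(df: pd.DataFrame) -> list[RescueLine]:
    """Build lines from a long (per-worm) or summary dataframe.

    Long format: transgene_id, genotype, worm_id, progeny_total
    (optionally control_progeny rows flagged by worm_id prefix "control").
    Summary format: transgene_id, genotype, mean, sem, n — mean cells may
    read "<1", which is ingested as the interval (0,1), value 0.5, flagged.
    """
    cols = set(df.columns)
    lines: list[RescueLine] = []
    if {"worm_id", "progeny_total"} <= cols:
        for (tg, gt), grp in df.groupby(["transgene_id", "genotype"], sort=False):
            is_control = grp["worm_id"].astype(str).str.startswith("control")
            counts = grp.loc[~is_control, "progeny_total"].astype(int).tolist()
            controls = grp.loc[is_control, "progeny_total"].astype(int).tolist()
            lines.append(
                RescueLine.from_counts(
                    str(tg), str(gt), counts, controls if controls else None
                )
            )
    elif {"mean", "sem", "n"} <= cols:
        for _, row in df.iterrows():
            raw = str(row["mean"]).strip()
            flags: tuple[str, ...] = ()
            if raw == "<1":
                mean, sem = LT1_VALUE, 0.0
                flags = ("lt1-interval",)
            else:
                mean = float(raw)
                sem = 0.0 if pd.isna(row["sem"]) or row["sem"] == "" else float(row["sem"])
            lines.append(
                RescueLine.from_summary(
                    str(row["transgene_id"]), str(row["genotype"]), mean, sem,
                    int(row["n"]), flags,
                )
            )
    else:
        raise RescueDataError(
            "dataframe must be long (worm_id, progeny_total) or summary "
            "(mean, sem, n) format"
        )
    if not lines:
        raise RescueDataError("no rescue lines in input")
    return lines


def load_brood_tables(table: int | None = None) -> pd.DataFrame:
    """The packaged transgenic-rescue summary tables (printed line means).

    Columns: table, transgene_id, genotype, mean, sem, n.  ``table``
    selects one of the three assay tables (cysteine substitutions;
    the C678/C681 compensation set; the cross-species exon swaps).
    """
    with importlib.resources.files("ringscape.data").joinpath(
        "brood_tables.csv"
    ).open() as fh:
        df = pd.read_csv(fh, dtype={"mean": str})
    if table is not None:
        df = df[df["table"] == table].reset_index(drop=True)
    return df


class RescueModel:
    """Rescue-assay model over a table of transgenic lines.

    Parameters
    ----------
    lines : sequence of RescueLine
    reference : genotype label of the wild-type-transgene arm
    weighting : "unweighted" (mean of line means; default) or "n-weighted"
    thresholds : RescueThresholds for classification

    ``fit`` estimates a rescue fraction per genotype with an optional
    percentile-bootstrap interval and returns a :class:`RescueResults`.
    """

    def __init__(
        self,
        lines: Sequence[RescueLine],
        reference: str = "wild type",
        weighting: str = "unweighted",
        thresholds: RescueThresholds | None = None,
        apply_recombinant_filter: bool = True,
    ):
        if apply_recombinant_filter:
            lines, self.exclusion_log = recombinant_filter(lines)
        else:
            self.exclusion_log = []
        self.lines = list(lines)
        self.reference = reference
        self.weighting = weighting
        self.thresholds = thresholds or RescueThresholds()
        self._by_genotype: dict[str, list[RescueLine]] = {}
        for ln in self.lines:
            self._by_genotype.setdefault(ln.genotype_label, []).append(ln)
        if reference not in self._by_genotype:
            raise RescueDataError(f"reference genotype {reference!r} absent from data")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RescueModel":
        return cls(lines_from_dataframe(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RescueModel":
        return cls.from_dataframe(pd.read_csv(path, dtype={"mean": str}), **kwargs)

    def fit(self, bootstrap: int = 0, seed: int = 0) -> "RescueResults":
        ref_lines = self._by_genotype[self.reference]
        summaries: dict[str, GenotypeSummary] = {}
        intervals: dict[str, tuple[float, float] | None] = {}
        for gt, lines in self._by_genotype.items():
            summaries[gt] = genotype_rescue(
                lines, ref_lines, self.weighting, self.thresholds
            )
            if bootstrap:
                intervals[gt] = bootstrap_ci(
                    lines, ref_lines, B=bootstrap, seed=seed, weighting=self.weighting
                )
            else:
                intervals[gt] = None
        return RescueResults(self, summaries, intervals)


class RescueResults:
    """Estimates from a fitted :class:`RescueModel`."""

    def __init__(self, model, summaries, intervals):
        self.model = model
        self.summaries: dict[str, GenotypeSummary] = summaries
        self.intervals: dict[str, tuple[float, float] | None] = intervals

    def __getitem__(self, genotype: str) -> GenotypeSummary:
        return self.summaries[genotype]

    def compensation(
        self, single_a: str, single_b: str, double: str, **kwargs
    ) -> CompensationResult:
        try:
            a, b, d = (self.summaries[g] for g in (single_a, single_b, double))
        except KeyError as e:
            raise RescueDataError(f"genotype {e.args[0]!r} missing from results")
        return compensation_test(a, b, d, rescue_thresholds=self.model.thresholds, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gt, s in self.summaries.items():
            ci = self.intervals.get(gt)
            rows.append(
                {
                    "genotype": gt,
                    "lines": len(s.line_means),
                    "grand_mean": s.grand_mean,
                    "rescue_fraction": s.rescue_fraction,
                    "rescue_percent": s.rescue_percent,
                    "classification": s.classification,
                    "ci_low": None if ci is None else ci[0],
                    "ci_high": None if ci is None else ci[1],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        header = (
            f"Transgenic rescue summary (reference: {self.model.reference}, "
            f"{self.model.weighting})"
        )
        with pd.option_context("display.float_format", lambda v: f"{v:.3f}"):
            body = df.to_string(index=False)
        return f"{header}\n{'=' * len(header)}\n{body}"
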