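"""The partition-stability experiment.

The design: six experiment runs on one dataset — three with random
image-level splits, three with case-wise splits — identical in everything
but the split seed.  Each run fits the baseline detector on its training
subset, evaluates on its test subset, and yields one metrics row; each
scheme's three rows are aggregated to Average and STD rows (sample SD).
The question is whether the case-wise scheme's run-to-run SD of TPR is
smaller, i.e. whether preventing case leakage stabilizes the measured
performance.

Because a 3-run SD is itself extremely noisy, the module also provides a
*meta-study*: the whole 3+3 design repeated on many independently generated
synthetic datasets, reporting in what fraction of meta-repeats the
case-wise SD is the smaller one, at strong intra-case correlation and at
zero correlation (the falsification control — with independent views the
two schemes differ only in sampling granularity and the effect, if any,
must vanish).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mammopart.dataio import LesionMask, Mammogram, Manifest
from mammopart.detector import default_grid, detect, fit_baseline
from mammopart.errors import ValidationError
from mammopart.evaluate import (
    AggregateRow,
    MetricSummary,
    aggregate_runs,
    dice_score,
    format_aggregate,
    format_row,
    match_detections,
    summarize_run,
)
from mammopart.mms_pcm import PseudoColorImage, compute_pcm, scales_from_spacing
from mammopart.partition import (
    LeakageReport,
    PartitionAssignment,
    audit_leakage,
    case_wise_split,
    random_split,
)
from mammopart.synthetic_data import SyntheticConfig, generate_dataset

#: Canonical full-scale partition sizes (train, val, test) for a 410-image census.
FULL_SCALE_COUNTS = (280, 65, 65)


def scaled_targets(n_images: int) -> tuple[int, int, int]:
    """Scale the canonical 280/65/65 proportions to ``n_images``."""
    train = int(round(n_images * FULL_SCALE_COUNTS[0] / sum(FULL_SCALE_COUNTS)))
    val = int(round(n_images * FULL_SCALE_COUNTS[1] / sum(FULL_SCALE_COUNTS)))
    return (n_images - val - (n_images - train - val), val, n_images - train - val)


@dataclass
class ExperimentConfig:
    """One scheme's repeated-run configuration."""

    scheme: str  # "random" or "case_wise"
    seeds: list[int]
    target_counts: tuple[int, int, int]
    iou_threshold: float = 0.2
    grid: dict | None = None  # baseline search grid; None = physically derived
    fp_penalty: float = 0.1
    #: optional external detector: callable(pcm, image_id) -> DetectionSet.
    #: When set, fitting is skipped and the adapter is used as-is (e.g. the
    #: ground-truth oracle adapter for pipeline regression tests).
    adapter: object | None = None

    @property
    def n_repeats(self) -> int:
        return len(self.seeds)


@dataclass
class ExperimentReport:
    """Side-by-side Table-style comparison of the two schemes."""

    random_rows: list[MetricSummary]
    case_rows: list[MetricSummary]
    random_aggregate: AggregateRow
    case_aggregate: AggregateRow
    random_leakage: list[LeakageReport] = field(default_factory=list)
    case_leakage: list[LeakageReport] = field(default_factory=list)

    @property
    def sd_tpr_random(self) -> float:
        return self.random_aggregate.tpr_std

    @property
    def sd_tpr_case(self) -> float:
        return self.case_aggregate.tpr_std

    @property
    def sd_dice_random(self) -> float:
        return self.random_aggregate.dice_mean_std

    @property
    def sd_dice_case(self) -> float:
        return self.case_aggregate.dice_mean_std

    def to_table(self) -> pd.DataFrame:
        """Rows ordered R1..Rn, Average, STD, C1..Cn, Average, STD."""
        rows = []

        def metric_cells(s: MetricSummary) -> dict:
            return {
                "tpr": round(s.tpr, 3),
                "fppi": round(s.fp_per_image, 2),
                "false_discovery_fraction": round(s.false_discovery_fraction, 3),
                "dice_mean": round(s.dice_mean, 3),
                "dice_std": round(s.dice_std, 3),
            }

        for label, summaries, agg in (
            ("R", self.random_rows, self.random_aggregate),
            ("C", self.case_rows, self.case_aggregate),
        ):
            for i, s in enumerate(summaries, start=1):
                rows.append({"experiment": f"{label}{i}", **metric_cells(s)})
            rows.append(
                {
                    "experiment": "Average",
                    "tpr": round(agg.tpr_mean, 3),
                    "fppi": round(agg.fppi_mean, 2),
                    "false_discovery_fraction": float("nan"),
                    "dice_mean": round(agg.dice_mean_mean, 3),
                    "dice_std": round(agg.dice_std_mean, 3),
                }
            )
            rows.append(
                {
                    "experiment": "STD",
                    "tpr": round(agg.tpr_std, 3),
                    "fppi": round(agg.fppi_std, 2),
                    "false_discovery_fraction": float("nan"),
                    "dice_mean": round(agg.dice_mean_std, 3),
                    "dice_std": round(agg.dice_std_std, 3),
                }
            )
        return pd.DataFrame(rows)

    def format(self) -> str:
        lines = ["Experiment\tTPR @ FPPI\tDice"]
        for label, summaries, agg in (
            ("R", self.random_rows, self.random_aggregate),
            ("C", self.case_rows, self.case_aggregate),
        ):
            for i, s in enumerate(summaries, start=1):
                lines.append(f"{label}{i}\t{format_row(s)}")
            avg, std = format_aggregate(agg)
            lines.append(f"Average\t{avg}")
            lines.append(f"STD\t{std}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Running experiments
# ---------------------------------------------------------------------------


def evaluate_split(
    assignment: PartitionAssignment,
    manifest: Manifest,
    pcms: dict[str, PseudoColorImage],
    masks: dict[str, LesionMask],
    config: ExperimentConfig,
) -> MetricSummary:
    """Fit the baseline on the split's train subset, evaluate on its test subset."""
    test_ids = assignment.subset("test")
    if config.adapter is not None:
        predict = lambda image_id: config.adapter(pcms[image_id], image_id)  # noqa: E731
    else:
        spacing = manifest.records[0].pixel_spacing_mm
        grid = config.grid if config.grid is not None else default_grid(spacing)
        train_ids = assignment.subset("train")
        model = fit_baseline(
            [pcms[i] for i in train_ids],
            [masks[i] for i in train_ids],
            grid,
            fp_penalty=config.fp_penalty,
            iou_threshold=config.iou_threshold,
        )
        predict = lambda image_id: detect(model, pcms[image_id])  # noqa: E731
    matches = []
    dices: list[float | None] = []
    for image_id in test_ids:
        det = predict(image_id)
        truth = masks[image_id]
        matches.append(match_detections(det, truth, config.iou_threshold))
        if truth.mask.any():
            dices.append(dice_score(det.union_mask(truth.mask.shape), truth.mask))
        else:
            dices.append(None)
    return summarize_run(matches, dices)


def run_experiment(
    manifest: Manifest,
    pcms: dict[str, PseudoColorImage],
    masks: dict[str, LesionMask],
    config: ExperimentConfig,
) -> list[MetricSummary]:
    """One scheme's repeats: for each seed, split -> fit -> detect -> summarize.

    Everything except the split seed is held fixed across repeats.
    """
    summaries = []
    for seed in config.seeds:
        assignment = _split(manifest, config, seed)
        summaries.append(evaluate_split(assignment, manifest, pcms, masks, config))
    return summaries


def _split(manifest: Manifest, config: ExperimentConfig, seed: int) -> PartitionAssignment:
    if config.scheme == "random":
        return random_split(manifest, config.target_counts, seed)
    if config.scheme == "case_wise":
        return case_wise_split(manifest, config.target_counts, seed)
    raise ValidationError(f"unknown scheme {config.scheme!r}")


def compare_schemes(
    random_rows: list[MetricSummary],
    case_rows: list[MetricSummary],
    random_leakage: list[LeakageReport] | None = None,
    case_leakage: list[LeakageReport] | None = None,
) -> ExperimentReport:
    """Aggregate each scheme's rows into the side-by-side report."""
    return ExperimentReport(
        random_rows=list(random_rows),
        case_rows=list(case_rows),
        random_aggregate=aggregate_runs(random_rows),
        case_aggregate=aggregate_runs(case_rows),
        random_leakage=random_leakage or [],
        case_leakage=case_leakage or [],
    )


def run_full_comparison(
    manifest: Manifest,
    pcms: dict[str, PseudoColorImage],
    masks: dict[str, LesionMask],
    seeds: list[int],
    target_counts: tuple[int, int, int],
    *,
    grid: dict | None = None,
) -> ExperimentReport:
    """The complete 3+3 (or n+n) design on one dataset, with leakage audits."""
    reports = {}
    leakages = {}
    for scheme in ("random", "case_wise"):
        config = ExperimentConfig(
            scheme=scheme, seeds=list(seeds), target_counts=target_counts, grid=grid
        )
        leakages[scheme] = [
            audit_leakage(_split(manifest, config, s), manifest) for s in seeds
        ]
        reports[scheme] = run_experiment(manifest, pcms, masks, config)
    return compare_schemes(
        reports["random"],
        reports["case_wise"],
        random_leakage=leakages["random"],
        case_leakage=leakages["case_wise"],
    )


# ---------------------------------------------------------------------------
# Desk-scale meta-study
# ---------------------------------------------------------------------------


def desk_scale_config(
    *, intra_case_correlation: float = 0.9, seed: int = 0
) -> SyntheticConfig:
    """Reduced-footprint study conditions for the repeated meta-study.

    Same statistical structure as the full-scale defaults (mass prevalence,
    physical mass-area range, 4 correlated views per case) at a smaller
    census and coarser pixel grid so a full 3+3 design runs in seconds.
    """
    return SyntheticConfig(
        n_cases=24,
        image_shape=(104, 128),
        pixel_spacing_mm=2.2,
        intra_case_correlation=intra_case_correlation,
        seed=seed,
    )


def precompute_pcms(
    images: dict[str, Mammogram],
    pixel_spacing_mm: float,
    n_orientations: int = 8,
) -> dict[str, PseudoColorImage]:
    """MMS + pseudo-color for every image, at sieve scales derived from the
    pixel spacing."""
    scales = scales_from_spacing(pixel_spacing_mm, n_orientations=n_orientations)
    return {
        image_id: compute_pcm(m.pixels, scales, image_id=image_id)
        for image_id, m in images.items()
    }


@dataclass
class MetaStudyResult:
    """Outcome of repeating the 3+3 design on independent synthetic datasets."""

    intra_case_correlation: float
    sd_tpr_random: list[float]
    sd_tpr_case: list[float]
    mean_tpr_random: list[float]
    mean_tpr_case: list[float]
    leaked_cases_random: list[float]  # mean leaked cases per random repeat

    @property
    def n_meta(self) -> int:
        return len(self.sd_tpr_random)

    @property
    def n_case_le_random(self) -> int:
        return sum(c <= r for r, c in zip(self.sd_tpr_random, self.sd_tpr_case))

    @property
    def fraction_case_le_random(self) -> float:
        return self.n_case_le_random / self.n_meta

    def sign_test_pvalue(self) -> float:
        """Two-sided sign test of 'case SD < random SD' against p = 0.5,
        ties discarded."""
        from scipy.stats import binomtest

        wins = sum(c < r for r, c in zip(self.sd_tpr_random, self.sd_tpr_case))
        losses = sum(c > r for r, c in zip(self.sd_tpr_random, self.sd_tpr_case))
        if wins + losses == 0:
            return 1.0
        return float(binomtest(wins, wins + losses, 0.5).pvalue)


def meta_study(
    *,
    intra_case_correlation: float,
    n_meta: int = 20,
    n_repeats: int = 3,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
    n_orientations: int = 8,
) -> MetaStudyResult:
    """Repeat the n+n design on ``n_meta`` independent synthetic datasets.

    Each meta-repeat generates a fresh dataset (new census seed), computes
    PCMs once, and runs ``n_repeats`` random-split and ``n_repeats``
    case-wise experiments that differ only in split seed.
    """
    rng = np.random.default_rng(seed)
    result = MetaStudyResult(
        intra_case_correlation=intra_case_correlation,
        sd_tpr_random=[],
        sd_tpr_case=[],
        mean_tpr_random=[],
        mean_tpr_case=[],
        leaked_cases_random=[],
    )
    for _ in range(n_meta):
        census_seed = int(rng.integers(2**31))
        if base_config is None:
            config = desk_scale_config(
                intra_case_correlation=intra_case_correlation, seed=census_seed
            )
        else:
            config = SyntheticConfig(
                **{
                    **base_config.__dict__,
                    "intra_case_correlation": intra_case_correlation,
                    "seed": census_seed,
                }
            )
        manifest, images, masks = generate_dataset(config)
        pcms = precompute_pcms(images, config.pixel_spacing_mm, n_orientations)
        targets = scaled_targets(len(manifest))
        split_seeds = [int(rng.integers(2**31)) for _ in range(n_repeats)]
        report = run_full_comparison(manifest, pcms, masks, split_seeds, targets)
        result.sd_tpr_random.append(report.sd_tpr_random)
        result.sd_tpr_case.append(report.sd_tpr_case)
        result.mean_tpr_random.append(report.random_aggregate.tpr_mean)
        result.mean_tpr_case.append(report.case_aggregate.tpr_mean)
        result.leaked_cases_random.append(
            float(np.mean([lr.n_leaked_cases for lr in report.random_leakage]))
        )
        assert all(lr.n_leaked_cases == 0 for lr in report.case_leakage)
    return result
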