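"""Expression filters of the bidirectional-promoter pair screen.

Given candidate lncRNA/protein-coding pairs and a stimulation time-course
expression matrix, apply the screen's filters: robust expression, greater
than twofold response in either direction at some time point (with a
replicate t-test when replicates allow), and concordance of the two genes'
fold-change profiles (Spearman).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenePair, TranscriptModel, find_candidate_pairs
from .expression_kinetics import two_sample_ttest

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "ScreenResult",
    "fold_change",
    "differential_filter",
    "robust_expression_filter",
    "spearman_rho",
    "run_screen",
]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one expression column."""

    sample: str
    time: float
    replicate: int
    condition: str = "IFN"
    unit: str = "h"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


class ExpressionMatrix:
    """Gene x sample abundance matrix with per-sample time/replicate metadata.

    ``values`` is a pandas DataFrame (index: gene ids, columns: sample names,
    non-negative TPM-like units); ``samples`` the matching metadata.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        samples = list(samples)
        if list(values.columns) != [s.sample for s in samples]:
            raise ValueError("sample metadata does not match matrix columns")
        if values.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if (values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        self.values = values
        self.samples = samples

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def times(self, condition: str = "IFN") -> list[float]:
        return sorted({s.time for s in self.samples if s.condition == condition})

    def replicate_values(
        self, gene: str, time: float, condition: str = "IFN"
    ) -> np.ndarray:
        """Replicate abundances of one gene at one time point."""
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        cols = [
            s.sample
            for s in self.samples
            if s.condition == condition and s.time == time
        ]
        if not cols:
            raise KeyError(f"no samples at time {time} for condition {condition!r}")
        return self.values.loc[gene, cols].to_numpy(dtype=float)

    # -- I/O: tab-separated matrix + metadata sidecar ----------------------

    def to_tsv(self) -> tuple[str, str]:
        mat = self.values.to_csv(sep="\t", index_label="gene")
        meta = pd.DataFrame(
            [
                {
                    "sample": s.sample,
                    "time": s.time,
                    "unit": s.unit,
                    "replicate": s.replicate,
                    "condition": s.condition,
                }
                for s in self.samples
            ]
        ).to_csv(sep="\t", index=False)
        return mat, meta

    @classmethod
    def from_tsv(cls, matrix_text: str, meta_text: str) -> "ExpressionMatrix":
        values = pd.read_csv(io.StringIO(matrix_text), sep="\t", index_col="gene")
        meta = pd.read_csv(io.StringIO(meta_text), sep="\t")
        samples = [
            SampleMeta(
                sample=str(r["sample"]),
                time=float(r["time"]),
                replicate=int(r["replicate"]),
                condition=str(r["condition"]),
                unit=str(r["unit"]),
            )
            for _, r in meta.iterrows()
        ]
        return cls(values, samples)


@dataclass
class ScreenResult:
    """One candidate pair with its per-filter outcomes."""

    pair: GenePair
    times: list[float]
    lnc_log2fc_profile: list[float]
    pc_log2fc_profile: list[float]
    concordance_rho: float
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.passes.values())


def fold_change(
    expr: ExpressionMatrix,
    gene: str,
    time: float,
    baseline_time: float = 0.0,
    pseudocount: float = 0.5,
    condition: str = "IFN",
) -> float:
    """Ratio of replicate-mean abundance at ``time`` vs ``baseline_time``.

    The pseudocount is added to both means to guard zero baselines.
    """
    a = expr.replicate_values(gene, time, condition)
    b = expr.replicate_values(gene, baseline_time, condition)
    return (float(a.mean()) + pseudocount) / (float(b.mean()) + pseudocount)


def differential_filter(profile: Sequence[float], threshold: float = 2.0) -> bool:
    """True iff any fold in the profile exceeds the threshold in either
    direction (strictly > threshold or strictly < 1/threshold)."""
    profile = list(profile)
    if not profile:
        raise ValueError("profile must be non-empty")
    return any(f > threshold or f < 1.0 / threshold for f in profile)


def robust_expression_filter(
    expr: ExpressionMatrix,
    gene: str,
    min_level: float = 1.0,
    min_samples: int = 2,
) -> bool:
    """True iff the gene reaches ``min_level`` in at least ``min_samples``
    samples (any condition)."""
    if gene not in expr.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    row = expr.values.loc[gene].to_numpy(dtype=float)
    return int((row >= min_level).sum()) >= min_samples


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (flagged undefined, not an error) when either argument has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def _gene_response(
    expr: ExpressionMatrix,
    gene: str,
    times: Sequence[float],
    fc_threshold: float,
    pseudocount: float,
    alpha: float,
    condition: str,
) -> tuple[list[float], bool, int]:
    """Per-time folds, the differential-expression verdict, and the response
    direction (+1 induced, -1 repressed, 0 none).

    When every time point carries >= 2 replicates the fold criterion is
    paired with a per-time Student t-test (p < alpha); otherwise fold-only.
    """
    baseline = expr.replicate_values(gene, times[0], condition)
    per_time = {t: expr.replicate_values(gene, t, condition) for t in times[1:]}
    use_ttest = len(baseline) >= 2 and all(len(v) >= 2 for v in per_time.values())
    folds = [
        (float(per_time[t].mean()) + pseudocount)
        / (float(baseline.mean()) + pseudocount)
        for t in times[1:]
    ]
    significant = []  # folds that clear both the fold and (optional) t-test gates
    for t, fold in zip(times[1:], folds):
        if not (fold > fc_threshold or fold < 1.0 / fc_threshold):
            continue
        if use_ttest and two_sample_ttest(baseline, per_time[t]) >= alpha:
            continue
        significant.append(fold)
    de = bool(significant)
    if de:
        strongest = max(significant, key=lambda f: abs(math.log2(f)))
        direction = 1 if strongest > 1 else -1
    else:
        direction = 0
    return folds, de, direction


def run_screen(
    transcripts: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    max_gap: int = 2000,
    fc_threshold: float = 2.0,
    *,
    min_level: float = 1.0,
    min_samples: int = 2,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
    condition: str = "IFN",
    use_tss_distance: bool = False,
) -> list[ScreenResult]:
    """Run the full screen: proximity pairs, per-gene expression filters,
    and pair concordance.  Every candidate is returned with its flags; the
    passing subset is ``[r for r in results if r.passed]``.
    """
    pairs = find_candidate_pairs(
        transcripts, max_gap, use_tss_distance=use_tss_distance
    )
    gene_ids = set(expr.genes)
    annotated = {t.gene_id for t in transcripts}
    if pairs and not (annotated & gene_ids):
        raise ValueError("no gene ids shared between annotation and matrix")
    times = expr.times(condition)
    results = []
    for pair in pairs:
        if pair.lnc.gene_id not in gene_ids or pair.pc.gene_id not in gene_ids:
            continue
        lnc_folds, lnc_de, lnc_dir = _gene_response(
            expr, pair.lnc.gene_id, times, fc_threshold, pseudocount, alpha, condition
        )
        pc_folds, pc_de, pc_dir = _gene_response(
            expr, pair.pc.gene_id, times, fc_threshold, pseudocount, alpha, condition
        )
        lnc_l2 = [math.log2(f) for f in lnc_folds]
        pc_l2 = [math.log2(f) for f in pc_folds]
        rho = (
            spearman_rho(lnc_l2, pc_l2)
            if len(lnc_l2) >= 3
            else float("nan")
        )
        passes = {
            "robust_lnc": robust_expression_filter(
                expr, pair.lnc.gene_id, min_level, min_samples
            ),
            "robust_pc": robust_expression_filter(
                expr, pair.pc.gene_id, min_level, min_samples
            ),
            "de_lnc": lnc_de,
            "de_pc": pc_de,
            "concordant": bool(
                lnc_de
                and pc_de
                and lnc_dir == pc_dir
                and not math.isnan(rho)
                and rho > 0
            ),
        }
        results.append(
            ScreenResult(
                pair=pair,
                times=list(times[1:]),
                lnc_log2fc_profile=lnc_l2,
                pc_log2fc_profile=pc_l2,
                concordance_rho=rho,
                passes=passes,
            )
        )
    return results


def screen_table(results: Sequence[ScreenResult]) -> str:
    """Screen report as a tab-separated table."""
    cols = [
        "chrom",
        "lnc_gene",
        "pc_gene",
        "orientation",
        "tss_distance",
        "gap_distance",
        "concordance_rho",
        "robust_lnc",
        "robust_pc",
        "de_lnc",
        "de_pc",
        "concordant",
        "passed",
    ]
    lines = ["\t".join(cols)]
    for r in results:
        p = r.pair
        lines.append(
            "\t".join(
                map(
                    str,
                    [
                        p.lnc.chrom,
                        p.lnc.gene_id,
                        p.pc.gene_id,
                        p.orientation,
                        p.tss_distance,
                        p.gap_distance,
                        f"{r.concordance_rho:.4f}",
                        *[r.passes[k] for k in cols[7:12]],
                        r.passed,
                    ],
                )
            )
        )
    return "\n".join(lines) + "\n"


def screen_json(results: Sequence[ScreenResult]) -> str:
    """Screen report as JSON."""
    out = []
    for r in results:
        p = r.pair
        out.append(
            {
                "lnc_gene": p.lnc.gene_id,
                "pc_gene": p.pc.gene_id,
                "orientation": p.orientation,
                "tss_distance": p.tss_distance,
                "gap_distance": p.gap_distance,
                "times": r.times,
                "lnc_log2fc_profile": r.lnc_log2fc_profile,
                "pc_log2fc_profile": r.pc_log2fc_profile,
                "concordance_rho": None
                if math.isnan(r.concordance_rho)
                else r.concordance_rho,
                "passes": r.passes,
                "passed": r.passed,
            }
        )
    return json.dumps(out, indent=2)
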