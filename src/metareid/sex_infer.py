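"""Genetic-sex prediction from the Y-to-X normalized read-depth ratio.

Read counts per chromosome (restricted to non-pseudo-autosomal regions for
X and Y, so depth reflects copy number) are normalized twice: by the total
read count of the library, then by chromosome length. The Y/X ratio of the
resulting normalized depths sits near 1 in males (one copy of each) and
near 0 in females (two X, no Y beyond mismapping noise). A single-feature
logistic regression on the ratio gives a probability and a decision
boundary r*; a reference boundary of 0.43 is shipped for use without
training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .panel_io import RegionMask, read_bed_mask

logger = logging.getLogger("metareid")

#: Reference Y/X decision boundary for use without training data.
DEFAULT_THRESHOLD_RATIO = 0.43
_DEFAULT_STEEPNESS = 25.0  # logistic slope for the shipped threshold-only model


class SexInferenceError(ValueError):
    pass


@dataclass
class DepthProfile:
    """Per-chromosome raw counts, normalized counts and normalized depths."""

    raw: dict[str, int]
    normalized_count: dict[str, float]
    normalized_depth: dict[str, float]

    @property
    def yx_ratio(self) -> float | None:
        """Normalized-depth ratio Y/X; None when X depth is zero."""
        x = self.normalized_depth.get("X", 0.0)
        y = self.normalized_depth.get("Y", 0.0)
        if x <= 0.0:
            return None
        return y / x


@dataclass
class SexModel:
    """Logistic model P(male) = 1 / (1 + exp(-(intercept + coef * ratio)))."""

    intercept: float
    coefficient: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise SexInferenceError("coefficient must be positive (male coded 1)")

    @property
    def threshold_ratio(self) -> float:
        """Decision boundary r*: the ratio where P(male) = 0.5."""
        return -self.intercept / self.coefficient

    def probability_male(self, ratio: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(self.intercept + self.coefficient * ratio))))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficient": self.coefficient,
                    "threshold_ratio": self.threshold_ratio,
                },
                handle,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SexModel":
        with open(path) as handle:
            data = json.load(handle)
        return cls(intercept=data["intercept"], coefficient=data["coefficient"])


def default_model() -> SexModel:
    """The shipped reference model with decision boundary Y/X = 0.43."""
    return SexModel(
        intercept=-_DEFAULT_STEEPNESS * DEFAULT_THRESHOLD_RATIO,
        coefficient=_DEFAULT_STEEPNESS,
    )


def default_nonpar_mask() -> RegionMask:
    """Packaged GRCh37 non-pseudo-autosomal mask for X and Y."""
    with resources.as_file(
        resources.files("metareid.data").joinpath("grch37_nonpar.bed")
    ) as path:
        return read_bed_mask(path)


def depth_profile(
    counts: Mapping[str, int],
    total_reads: int,
    chrom_lengths: Mapping[str, int],
) -> DepthProfile:
    """Two-step normalization of per-chromosome read counts.

    ``counts`` for X and Y must already be restricted to the non-PAR mask,
    and ``chrom_lengths`` must give the matching (masked) lengths.
    """
    if total_reads < 1:
        raise SexInferenceError("total_reads must be >= 1")
    raw: dict[str, int] = {}
    norm_count: dict[str, float] = {}
    norm_depth: dict[str, float] = {}
    for chrom, count in counts.items():
        if count < 0:
            raise SexInferenceError(f"negative read count for {chrom}")
        length = chrom_lengths.get(chrom)
        if length is None or length <= 0:
            raise SexInferenceError(f"missing or non-positive length for {chrom}")
        raw[chrom] = int(count)
        norm_count[chrom] = count / total_reads
        norm_depth[chrom] = norm_count[chrom] / length
    return DepthProfile(raw=raw, normalized_count=norm_count, normalized_depth=norm_depth)


def fit_sex_model(ratios: Sequence[float], labels: Sequence[int]) -> SexModel:
    """Maximum-likelihood logistic fit of sex (male = 1) on the Y/X ratio.

    Uses a lightly ridge-penalized fit so perfectly separated training data
    still yield a finite boundary between the class extremes.
    """
    from sklearn.linear_model import LogisticRegression

    x = np.asarray(ratios, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise SexInferenceError("training data must contain both classes (0 and 1)")
    # scale the feature so the ridge penalty acts comparably for any ratio range
    scale = x.std() or 1.0
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=10_000)
    clf.fit(x / scale, y)
    coef = float(clf.coef_[0, 0]) / scale
    intercept = float(clf.intercept_[0])
    if coef <= 0:
        raise SexInferenceError("fitted coefficient is not positive; check labels")
    return SexModel(intercept=intercept, coefficient=coef)


def predict_sex(
    ratio: float | None, model: SexModel | None = None
) -> tuple[str, float | None]:
    """Classify a Y/X depth ratio as male/female with a probability.

    An undefined ratio (None, from zero X depth) or a ratio exactly at the
    decision boundary yields a no-call.
    """
    if model is None:
        model = default_model()
    if ratio is None or not np.isfinite(ratio):
        return "no-call", None
    if ratio < 0:
        raise SexInferenceError(f"ratio must be >= 0, got {ratio}")
    prob = model.probability_male(ratio)
    if ratio == model.threshold_ratio:
        return "no-call", prob
    return ("male" if ratio > model.threshold_ratio else "female"), prob
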