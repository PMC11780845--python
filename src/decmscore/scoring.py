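"""The two-part semi-quantitative scoring system for residual nuclei.

Part 1 — single suspicious point.  Each of the six morphometric parameters is
scored against a reference-nucleus benchmark (per-stain, per-nucleus-type
mean mu and SD sigma) on sigma intervals:

    3 : |x - mu| <= sigma          (within 1 sigma)
    2 : sigma < |x - mu| <= 2 sigma
    1 : 2 sigma < |x - mu| <= 3 sigma
    0 : |x - mu| > 3 sigma

Parameter scores are averaged within their dimension (size = area, perimeter;
shape = Feret, MinFeret, Feret ratio; color = average grayscale) and the
dimension scores are combined with weights into a total.  The closer a point
sits to the reference nucleus in all six parameters, the higher the total;
a point is called a nucleus when its total reaches a decision threshold.

Part 2 — whole section.  Three counts are binned into 0-4 component scores:
the total number of suspicious points, the number identified as nuclei by
part 1 (double-weighted: residual nuclei are the most direct evidence of
incomplete decellularization), and the number located in the extracellular
matrix.  The section total is s_overall + 2 * s_nucleus + s_ecm, range 0-16.

A consensus rule across the four stains turns per-stain section scores into a
sample-level call: alarms on at least ``k`` stains mean residual nuclei, a
single alarming stain points to impurity contamination (the classic false
positive of relying on one stain), and no alarms mean decellularized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometry import FeatureVector
from .stains import StainMethod

SIZE_PARAMS = ("area", "perimeter")
SHAPE_PARAMS = ("feret", "minferet", "feret_ratio")
COLOR_PARAMS = ("avg_gray",)

NUCLEUS = "nucleus"
IMPURITY = "impurity"


# ---------------------------------------------------------------------------
# reference benchmark


@dataclass(frozen=True)
class ReferenceBenchmark:
    """Per-parameter mean/SD of a reference nucleus population (mu +/- sigma)."""

    stain: StainMethod
    nucleus_type: str
    means: dict[str, float]
    sds: dict[str, float]
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("a benchmark needs at least 2 reference nuclei")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("SDs must be >= 0")


def build_benchmark(features: list[FeatureVector], stain: StainMethod | str,
                    nucleus_type: str) -> ReferenceBenchmark:
    """Sample mean and SD (n-1 denominator) of each parameter over reference
    nuclei of one type under one stain."""
    if len(features) < 2:
        raise ValueError("need >= 2 feature vectors to build a benchmark")
    table = np.array([fv.as_array() for fv in features], dtype=float)
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    names = FeatureVector.PARAMETERS
    return ReferenceBenchmark(
        stain=StainMethod.parse(stain),
        nucleus_type=nucleus_type,
        means=dict(zip(names, map(float, means))),
        sds=dict(zip(names, map(float, sds))),
        n=len(features),
    )


# ---------------------------------------------------------------------------
# part 1: single suspicious point


@dataclass(frozen=True)
class DimensionWeights:
    """Importance weights of the size / shape / color dimensions."""

    w_size: float = 1.0
    w_shape: float = 1.0
    w_color: float = 1.0

    def __post_init__(self):
        if min(self.w_size, self.w_shape, self.w_color) < 0:
            raise ValueError("weights must be nonnegative")
        if self.w_size + self.w_shape + self.w_color <= 0:
            raise ValueError("at least one weight must be positive")

    @property
    def max_total(self) -> float:
        return 3.0 * (self.w_size + self.w_shape + self.w_color)


def score_parameter(x: float, mu: float, sigma: float) -> int:
    """Sigma-interval score of one parameter value against the benchmark.

    Interval boundaries are closed toward the better score (|x - mu| exactly
    at k sigma earns the higher score).  A degenerate sigma of 0 scores 3 only
    for an exact match.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    dev = abs(x - mu)
    if sigma == 0:
        return 3 if dev == 0 else 0
    k = dev / sigma
    if k <= 1.0:
        return 3
    if k <= 2.0:
        return 2
    if k <= 3.0:
        return 1
    return 0


@dataclass(frozen=True)
class PointScore:
    """Scores of one suspicious point: per parameter, per dimension, total."""

    parameter_scores: dict[str, int]
    size: float
    shape: float
    color: float
    total: float
    weights: DimensionWeights = field(default_factory=DimensionWeights)

    @property
    def max_total(self) -> float:
        return self.weights.max_total


def score_point(fv: FeatureVector, benchmark: ReferenceBenchmark,
                weights: DimensionWeights | None = None) -> PointScore:
    """Score one point against a reference-nucleus benchmark.

    Dimension scores are the plain averages of their member parameter scores;
    the total is the weighted sum of the three dimension scores.
    """
    weights = weights or DimensionWeights()
    pscores = {
        name: score_parameter(getattr(fv, name), benchmark.means[name], benchmark.sds[name])
        for name in FeatureVector.PARAMETERS
    }
    size = sum(pscores[p] for p in SIZE_PARAMS) / len(SIZE_PARAMS)
    shape = sum(pscores[p] for p in SHAPE_PARAMS) / len(SHAPE_PARAMS)
    color = sum(pscores[p] for p in COLOR_PARAMS) / len(COLOR_PARAMS)
    total = weights.w_size * size + weights.w_shape * shape + weights.w_color * color
    return PointScore(parameter_scores=pscores, size=size, shape=shape,
                      color=color, total=total, weights=weights)


def default_point_threshold(weights: DimensionWeights | None = None) -> float:
    """Default nucleus call threshold: 60% of the maximum attainable total."""
    weights = weights or DimensionWeights()
    return 0.6 * weights.max_total


def classify_point(score: PointScore, threshold: float | None = None) -> str:
    """Call a scored point a nucleus iff its total reaches the threshold."""
    if threshold is None:
        threshold = default_point_threshold(score.weights)
    if not (0.0 <= threshold <= score.max_total):
        raise ValueError("threshold must lie in [0, max total]")
    return NUCLEUS if score.total >= threshold else IMPURITY


def calibrate_threshold(nucleus_totals, impurity_totals) -> float:
    """Pick the nucleus-call threshold maximizing balanced accuracy on labeled
    calibration totals.  Candidates are midpoints between observed totals."""
    nuc = np.asarray(nucleus_totals, dtype=float)
    imp = np.asarray(impurity_totals, dtype=float)
    if nuc.size == 0 or imp.size == 0:
        raise ValueError("both classes must be represented for calibration")
    values = np.unique(np.concatenate([nuc, imp]))
    candidates = np.concatenate([[values[0] - 0.5],
                                 (values[:-1] + values[1:]) / 2.0,
                                 [values[-1] + 0.5]])
    best_t, best_ba = candidates[0], -1.0
    for t in candidates:
        sens = (nuc >= t).mean()
        spec = (imp < t).mean()
        ba = 0.5 * (sens + spec)
        if ba > best_ba:
            best_ba, best_t = ba, float(t)
    return best_t


# ---------------------------------------------------------------------------
# part 2: whole section


@dataclass(frozen=True)
class SectionCounts:
    """Counts entering the whole-section score."""

    n_overall: int
    n_nucleus: int
    n_ecm: int

    def __post_init__(self):
        if min(self.n_overall, self.n_nucleus, self.n_ecm) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_nucleus > self.n_overall or self.n_ecm > self.n_overall:
            raise ValueError("component counts cannot exceed the overall count")


#: Upper edges of the 1/2/3 bins for each component (0 maps to score 0,
#: anything beyond the last edge to score 4).  Printed ranges overlap at
#: their endpoints ("0-10" vs "10-20"); endpoints resolve to the lower
#: category, giving integer bins [1,10], [11,20], [21,50], >50 etc.
SECTION_BIN_EDGES = {
    "overall": (10, 20, 50),
    "nucleus": (2, 5, 10),
    "ecm": (5, 10, 20),
}


def _bin_count(count: int, edges: tuple[int, int, int]) -> int:
    if count == 0:
        return 0
    for score, edge in enumerate(edges, start=1):
        if count <= edge:
            return score
    return 4


@dataclass(frozen=True)
class SectionScore:
    """Component scores and weighted total of one section."""

    s_overall: int
    s_nucleus: int
    s_ecm: int
    nucleus_weight: float
    total: float
    counts: SectionCounts


def score_section(counts: SectionCounts, nucleus_weight: float = 2.0) -> SectionScore:
    """Whole-section decellularization score.

    Components: overall suspicious points, points identified as nuclei
    (multiplied by ``nucleus_weight``, default 2) and points in the ECM.
    At the default weight the total spans 0-16.
    """
    s_overall = _bin_count(counts.n_overall, SECTION_BIN_EDGES["overall"])
    s_nucleus = _bin_count(counts.n_nucleus, SECTION_BIN_EDGES["nucleus"])
    s_ecm = _bin_count(counts.n_ecm, SECTION_BIN_EDGES["ecm"])
    total = s_overall + nucleus_weight * s_nucleus + s_ecm
    return SectionScore(s_overall=s_overall, s_nucleus=s_nucleus, s_ecm=s_ecm,
                        nucleus_weight=nucleus_weight, total=float(total), counts=counts)


# ---------------------------------------------------------------------------
# multi-stain consensus


DECELLULARIZED = "decellularized"
RESIDUAL_NUCLEI = "residual_nuclei"
CONTAMINATION_SUSPECT = "contamination_suspect"


@dataclass(frozen=True)
class ConsensusDecision:
    """Sample-level call from per-stain section scores."""

    decision: str
    alarms: dict[str, bool]
    insufficient_stains: bool = False


def consensus_sample_decision(section_totals: dict[StainMethod | str, float],
                              alarm_threshold: float = 6.0,
                              min_alarms: int = 2) -> ConsensusDecision:
    """Combine per-stain section totals into one decision.

    A stain "alarms" when its section total reaches ``alarm_threshold``.
    At least ``min_alarms`` alarming stains -> residual nuclei; exactly one
    alarming stain -> contamination suspect (impurities mimic nuclei under a
    single stain but not under independent staining chemistries); otherwise
    decellularized.  Fewer than two stains still yields a decision but with
    the ``insufficient_stains`` flag set.
    """
    if not section_totals:
        raise ValueError("no section scores provided")
    alarms = {str(StainMethod.parse(s).value): total >= alarm_threshold
              for s, total in section_totals.items()}
    n_alarm = sum(alarms.values())
    if n_alarm >= min_alarms:
        decision = RESIDUAL_NUCLEI
    elif n_alarm == 1:
        decision = CONTAMINATION_SUSPECT
    else:
        decision = DECELLULARIZED
    return ConsensusDecision(decision=decision, alarms=alarms,
                             insufficient_stains=len(section_totals) < 2)


# ---------------------------------------------------------------------------
# stratified sampling protocol


@dataclass(frozen=True)
class SamplingProtocol:
    """Stratified sampling: ``n_sections`` sections drawn at random from the
    positive sections of a staining group, then ``nuclei_per_section`` nuclei
    and ``impurities_per_section`` impurities per chosen section."""

    n_sections: int = 5
    nuclei_per_section: int = 5
    impurities_per_section: int = 5


def stratified_sample(sections, protocol: SamplingProtocol | None = None, rng=None):
    """Sample reference nuclei and impurities from positive sections.

    ``sections`` is a sequence of (nuclei, impurities) pairs of per-section
    object lists.  Sections are drawn uniformly without replacement among
    those holding enough objects of both kinds; objects are then drawn
    uniformly without replacement within each chosen section.  Returns
    (nuclei, impurities) — with the default protocol, 25 of each.
    """
    protocol = protocol or SamplingProtocol()
    rng = np.random.default_rng(rng)
    eligible = [i for i, (nuc, imp) in enumerate(sections)
                if len(nuc) >= protocol.nuclei_per_section
                and len(imp) >= protocol.impurities_per_section]
    if len(eligible) < protocol.n_sections:
        raise ValueError(
            f"need {protocol.n_sections} sections with >= "
            f"{protocol.nuclei_per_section} nuclei and "
            f">= {protocol.impurities_per_section} impurities; "
            f"only {len(eligible)} of {len(sections)} qualify")
    chosen = rng.choice(len(eligible), size=protocol.n_sections, replace=False)
    nuclei, impurities = [], []
    for idx in sorted(eligible[i] for i in chosen):
        nuc, imp = sections[idx]
        if protocol.nuclei_per_section:
            for j in rng.choice(len(nuc), size=protocol.nuclei_per_section, replace=False):
                nuclei.append(nuc[j])
        if protocol.impurities_per_section:
            for j in rng.choice(len(imp), size=protocol.impurities_per_section,
                               replace=False):
                impurities.append(imp[j])
    return nuclei, impurities
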