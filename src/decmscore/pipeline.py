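"""End-to-end orchestration: simulate -> detect -> measure -> score -> decide.

``run_pipeline`` executes the full synthetic study: it renders the group x
stain x section grid, detects suspicious points on every slide, measures the
six parameters of each point, builds the per-stain reference-nucleus
benchmarks by the stratified sampling protocol, runs both scoring parts,
combines stains into sample-level consensus decisions, and trains/evaluates
the feature classifier.  Every random draw flows from the master seed via
named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import classify as cls
from .detect import (DetectConfig, detect_suspicious_points, flag_ecm_location,
                     match_to_ground_truth, split_dataset, to_analysis_channel)
from .morphometry import FeatureVector, measure_object
from .scoring import (DimensionWeights, ReferenceBenchmark, SamplingProtocol,
                      SectionCounts, build_benchmark, calibrate_threshold,
                      consensus_sample_decision, default_point_threshold,
                      score_point, score_section, stratified_sample)
from .simulate import (NUCLEUS_CLASSES, StudyConfig, default_study_config,
                       generate_study)
from .stains import BRIGHTFIELD_STAINS, StainMethod

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Reproducibility surface of one full run; round-trips through JSON."""

    master_seed: int = 0
    stains: tuple[str, ...] = tuple(s.value for s in StainMethod)
    n_sections: int = 15
    image_size: tuple[int, int] = (384, 384)
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    point_threshold: float | None = None    # None -> 60% of the maximum total
    alarm_threshold: float = 6.0
    consensus_min_alarms: int = 2
    classifier_family: str = "linear"
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.n_sections < 1:
            raise ValueError("config requires at least one section per group")
        self.stains = tuple(StainMethod.parse(s).value for s in self.stains)
        if not self.stains:
            raise ValueError("at least one stain is required")

    def dimension_weights(self) -> DimensionWeights:
        return DimensionWeights(*self.weights)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        data = dict(data)
        for key in ("stains", "image_size", "weights", "split_ratios"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PointRecord:
    """One detected point with its measurement and ground-truth annotation."""

    group: str
    stain: StainMethod
    section: int
    point_id: int
    features: FeatureVector
    true_label: str | None          # nucleus_1 / nucleus_2 / dust / None (unmatched)
    in_ecm: bool


@dataclass
class RunReport:
    """Everything a run produced, traceable to the config hash."""

    config: RunConfig
    config_hash: str
    sections: pd.DataFrame          # one row per (group, stain, section)
    consensus: pd.DataFrame         # one row per (group, section)
    benchmarks: dict
    point_exercise: dict            # per-stain single-point scoring results
    classifier_metrics: cls.EvalMetrics | None
    detection: dict                 # recovery statistics
    version: str = __version__

    def summary(self) -> str:
        lines = [f"decmscore run {self.config_hash} (seed {self.config.master_seed})",
                 f"slides: {len(self.sections)}  "
                 f"stains: {', '.join(self.config.stains)}"]
        lines.append(f"detection recovery (visible ground truth): "
                     f"{100 * self.detection['recovery']:.1f}%  "
                     f"DAPI dust detections: {self.detection['dapi_dust_detections']}")
        grp = self.sections.groupby("group")["total"].mean()
        lines.append("mean section score by group: "
                     + "  ".join(f"{g}={v:.1f}" for g, v in grp.items()))
        if self.point_exercise:
            acc = self.point_exercise["overall_accuracy"]
            lines.append(f"single-point scoring accuracy (calibrated threshold): "
                         f"{100 * acc:.1f}%")
        if self.classifier_metrics is not None:
            m = self.classifier_metrics
            rec = "  ".join(f"{k}={v:.2f}" for k, v in m.recall.items())
            lines.append(f"classifier test accuracy: {m.accuracy:.3f}  recall: {rec}")
        counts = self.consensus["decision"].value_counts().to_dict()
        lines.append(f"consensus decisions: {counts}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def _measure_slide(spec, slide, detect_overrides=None) -> tuple[list[PointRecord], dict]:
    """Detect, ECM-flag, measure and ground-truth-match one slide."""
    config = DetectConfig(stain=spec.stain, **(detect_overrides or {}))
    channel = to_analysis_channel(slide.image, spec.stain)
    points = detect_suspicious_points(channel, config)
    flag_ecm_location(points, slide.ecm_mask)
    matches = match_to_ground_truth(points, slide.objects, channel.shape)

    records = []
    for p in points:
        fv = measure_object(p.full_mask(channel.shape), channel)
        truth = matches.get(p.id)
        records.append(PointRecord(
            group=spec.group, stain=spec.stain, section=spec.section,
            point_id=p.id, features=fv,
            true_label=slide.objects[truth].class_label if truth is not None else None,
            in_ecm=bool(p.in_ecm),
        ))

    visible = [o for o in slide.objects
               if not (spec.stain.is_fluorescent and o.class_label == "dust")]
    matched_truths = set(matches.values())
    stats = {
        "n_visible_truth": len(visible),
        "n_truth": len(slide.objects),
        "n_matched": len(matched_truths),
        "n_detected": len(points),
        "n_dust_detected": sum(
            1 for t in matched_truths if slide.objects[t].class_label == "dust"),
    }
    return records, stats


def _benchmark_sections(records: list[PointRecord], group: str, stain: StainMethod,
                        nucleus_class: str, n_sections: int):
    """Per-section (nuclei, impurities) lists for the stratified protocol."""
    sections = []
    for sec in range(n_sections):
        here = [r for r in records
                if r.group == group and r.stain == stain and r.section == sec]
        nuclei = [r for r in here if r.true_label == nucleus_class]
        dust = [r for r in here if r.true_label == "dust"]
        sections.append((nuclei, dust))
    return sections


def _single_point_exercise(records, benchmarks, sampled_ids, weights, stain, rng):
    """Calibrated nucleus-vs-dust accuracy of the part-1 scoring table.

    Scores every benchmark-class nucleus and dust point *not* used to build
    the benchmark, splits them in half for threshold calibration vs testing,
    and reports test accuracy plus the mean totals behind the direction check
    (dust far below reference nuclei).
    """
    out = {}
    for ntype in NUCLEUS_CLASSES:
        bench = benchmarks.get((stain, ntype))
        if bench is None:
            continue
        held_out_nuc = [r for r in records
                        if r.stain == stain and r.true_label == ntype
                        and id(r) not in sampled_ids]
        held_out_dust = [r for r in records
                         if r.stain == stain and r.true_label == "dust"
                         and id(r) not in sampled_ids]
        if len(held_out_nuc) < 4 or len(held_out_dust) < 4:
            continue
        nuc_tot = np.array([score_point(r.features, bench, weights).total
                            for r in held_out_nuc])
        dust_tot = np.array([score_point(r.features, bench, weights).total
                             for r in held_out_dust])
        cal_n, test_n = split_dataset(nuc_tot, (0.5, 0.5), rng)
        cal_d, test_d = split_dataset(dust_tot, (0.5, 0.5), rng)
        threshold = calibrate_threshold(cal_n, cal_d)
        correct = int((np.asarray(test_n) >= threshold).sum()) + \
            int((np.asarray(test_d) < threshold).sum())
        n_test = len(test_n) + len(test_d)
        out[ntype] = {
            "threshold": threshold,
            "test_accuracy": correct / n_test,
            "n_test": n_test,
            "mean_total_nucleus": float(nuc_tot.mean()),
            "mean_total_dust": float(dust_tot.mean()),
            "totals_nucleus": nuc_tot.tolist(),
            "totals_dust": dust_tot.tolist(),
        }
    return out


def run_pipeline(config: RunConfig | None = None,
                 study_config: StudyConfig | None = None) -> RunReport:
    """Execute the full synthetic study and return the report.

    Fully deterministic given ``config.master_seed``.  An explicit
    ``study_config`` overrides the default group grid (it must keep the two
    positive groups if benchmarks are to be built).
    """
    config = config or RunConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if study_config is None:
        study_config = default_study_config(master_seed=config.master_seed,
                                            n_sections=config.n_sections,
                                            image_size=config.image_size)
        study_config.stains = tuple(StainMethod.parse(s) for s in config.stains)
    study = generate_study(study_config)
    weights = config.dimension_weights()
    seeds = np.random.SeedSequence(config.master_seed)
    stream = {name: np.random.default_rng(s) for name, s in zip(
        ("protocol", "exercise", "split", "train"), seeds.spawn(4))}

    # ---- detect + measure every slide -------------------------------------
    logger.info("rendering and measuring %d slides", len(study))
    all_records: list[PointRecord] = []
    per_slide: dict[tuple, list[PointRecord]] = {}
    det_stats = {"matched": 0, "visible": 0, "dapi_dust": 0}
    for spec, slide in study.slides():
        records, stats = _measure_slide(spec, slide)
        per_slide[(spec.group, spec.stain, spec.section)] = records
        all_records.extend(records)
        det_stats["matched"] += stats["n_matched"]
        det_stats["visible"] += stats["n_visible_truth"]
        if spec.stain.is_fluorescent:
            det_stats["dapi_dust"] += stats["n_dust_detected"]

    # ---- reference benchmarks via the stratified protocol ------------------
    group_of = {"nucleus_1": "positive_1", "nucleus_2": "positive_2"}
    benchmarks: dict[tuple[StainMethod, str], ReferenceBenchmark] = {}
    sampled_ids: set[int] = set()
    # reduced grids sample fewer sections at the same 5-objects-per-section
    # density, so benchmarks shrink proportionally (full design: 5 x 5 = 25)
    n_proto = min(5, study_config.n_sections)
    for stain in study_config.stains:
        # DAPI cannot visualize dust, so its protocol samples nuclei only
        protocol = SamplingProtocol(
            n_sections=n_proto,
            impurities_per_section=0 if stain.is_fluorescent else 5)
        for ntype, group in group_of.items():
            if not any(g.name == group for g in study_config.groups):
                continue
            sections = _benchmark_sections(all_records, group, stain, ntype,
                                           study_config.n_sections)
            try:
                nuclei, dust = stratified_sample(sections, protocol, stream["protocol"])
            except ValueError:
                logger.warning("not enough objects to build the %s/%s benchmark",
                               stain.value, ntype)
                continue
            nuclei, dust = nuclei[:25], dust[:25]
            benchmarks[(stain, ntype)] = build_benchmark(
                [r.features for r in nuclei], stain, ntype)
            sampled_ids.update(id(r) for r in nuclei)
            sampled_ids.update(id(r) for r in dust)

    # ---- part 1 exercise: nucleus-vs-dust accuracy (brightfield stains) ----
    point_exercise: dict = {"per_stain": {}}
    accs = []
    for stain in study_config.stains:
        if stain not in BRIGHTFIELD_STAINS:
            continue  # DAPI cannot visualize dust; excluded from part 1
        res = _single_point_exercise(all_records, benchmarks, sampled_ids,
                                     weights, stain, stream["exercise"])
        if res:
            point_exercise["per_stain"][stain.value] = res
            accs.extend(v["test_accuracy"] for v in res.values())
    point_exercise["overall_accuracy"] = float(np.mean(accs)) if accs else float("nan")

    # ---- part 2: section scores -------------------------------------------
    threshold = (default_point_threshold(weights) if config.point_threshold is None
                 else config.point_threshold)
    rows = []
    for spec in study.specs:
        records = per_slide[(spec.group, spec.stain, spec.section)]
        stain_benches = [b for (s, _), b in benchmarks.items() if s == spec.stain]
        n_nucleus = 0
        for r in records:
            totals = [score_point(r.features, b, weights).total for b in stain_benches]
            if totals and max(totals) >= threshold:
                n_nucleus += 1
        counts = SectionCounts(n_overall=len(records), n_nucleus=n_nucleus,
                               n_ecm=sum(1 for r in records if r.in_ecm))
        sc = score_section(counts)
        rows.append({"group": spec.group, "stain": spec.stain.value,
                     "section": spec.section, "is_positive": spec.is_positive,
                     "n_overall": counts.n_overall, "n_nucleus": counts.n_nucleus,
                     "n_ecm": counts.n_ecm, "s_overall": sc.s_overall,
                     "s_nucleus": sc.s_nucleus, "s_ecm": sc.s_ecm,
                     "total": sc.total})
    sections = pd.DataFrame(rows)

    # ---- consensus across stains -------------------------------------------
    consensus_rows = []
    for (group, section), sub in sections.groupby(["group", "section"]):
        totals = dict(zip(sub["stain"], sub["total"]))
        decision = consensus_sample_decision(totals,
                                             alarm_threshold=config.alarm_threshold,
                                             min_alarms=config.consensus_min_alarms)
        consensus_rows.append({"group": group, "section": section,
                               "decision": decision.decision,
                               "n_alarms": sum(decision.alarms.values()),
                               "insufficient_stains": decision.insufficient_stains})
    consensus = pd.DataFrame(consensus_rows)

    # ---- learned classifier (brightfield stains, 6:2:2 split) --------------
    labeled = [cls.LabeledFeature(features=r.features, stain=r.stain,
                                  label=cls.NUCLEUS if r.true_label in NUCLEUS_CLASSES
                                  else cls.IMPURITY)
               for r in all_records
               if r.true_label is not None and r.stain in BRIGHTFIELD_STAINS]
    metrics = None
    if labeled:
        splits = split_dataset(labeled, config.split_ratios, stream["split"])
        for items, name in zip(splits, (cls.TRAIN, cls.VAL, cls.TEST)):
            for it in items:
                it.split = name
        train_items = [it for it in labeled if it.split == cls.TRAIN]
        try:
            model = cls.train_classifier(
                train_items, cls.ModelConfig(family=config.classifier_family),
                stream["train"])
            metrics = cls.evaluate_classifier(model, labeled, split=cls.TEST)
        except ValueError as err:
            logger.warning("classifier skipped: %s", err)

    detection = {
        "recovery": det_stats["matched"] / max(1, det_stats["visible"]),
        "dapi_dust_detections": det_stats["dapi_dust"],
        "n_points": len(all_records),
    }
    return RunReport(config=config, config_hash=config.config_hash(),
                     sections=sections, consensus=consensus,
                     benchmarks=benchmarks, point_exercise=point_exercise,
                     classifier_metrics=metrics, detection=detection)
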