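"""End-to-end analyses: table statistics and full synthetic experiments.

Two entry points mirror the two kinds of input the package handles:

* :func:`run_fixture_analysis` — statistics on a subject table alone (the
  packaged 52-subject cohort or any table in the same shape): every
  questionnaire/prediction correlation with decoded accuracy, permutation
  significance with FDR correction, pre-task RMSE, descriptive statistics,
  chance-level counts, the low-performer exclusion recomputation and the
  substance-group comparisons.

* :func:`run_synthetic_experiment` — generate an ERD-structured cohort,
  decode every subject (session-level and run-wise), then run the same
  correlation/evolution analysis against the *decoded* accuracies.

All randomness flows from explicit seeds recorded in the report; two runs
with the same configuration produce identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .table import SubjectTable, load_subject_table, assign_groups
from .simulate import GeneratorConfig, CohortConfig, generate_cohort
from .preprocess import bandpass, epoch
from .crossval import cross_validated_accuracy, run_wise_accuracy
from . import stats as st

__all__ = [
    "PipelineConfig",
    "run_fixture_analysis",
    "run_synthetic_experiment",
]

#: Table columns correlated with decoded accuracy, by family.
CONDITION_MEASURES = ("SLP", "NSLP", "CALM", "INT", "CONCENT", "BODY", "MENTAL")
SCORE_MEASURES = ("preAP", "ES", "AP")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable pipeline settings.

    ``generator``/``cohort`` hold keyword arguments for
    :class:`GeneratorConfig` and :class:`CohortConfig` (the cohort's skill
    distribution is given as ``skill_range: [lo, hi]`` -> uniform).
    """

    generator: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    decoding: dict = field(default_factory=lambda: {
        "band": [8.0, 30.0], "window": [0.4, 2.4],
        "m_filters": 10, "run_m_filters": 6,
        "k": 10, "n_test": 3, "stratified": True})
    stats: dict = field(default_factory=lambda: {"n_perm": 2500, "q": 0.1})
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(**self.generator)

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(self.cohort)
        lo, hi = kwargs.pop("skill_range", (0.1, 0.9))
        kwargs["skill_distribution"] = \
            lambda rng, n: rng.uniform(lo, hi, size=n)
        kwargs.setdefault("seed", self.seed)
        return CohortConfig(**kwargs)


def _correlation_block(table: SubjectTable, accuracy: np.ndarray,
                       n_perm: int, q: float, seed: int) -> dict:
    """Correlate every populated measure with accuracy; FDR-correct the family.

    Condition columns that are unpopulated or constant (all-NaN or a single
    repeated value — synthetic cohorts do not simulate them) are skipped.
    The score measures preAP/ES/AP are mandatory: a degenerate one raises.
    """

    def usable(name: str) -> bool:
        col = table.column(name)
        return bool(np.all(np.isfinite(col)) and np.ptp(col) > 0)

    measures = list(SCORE_MEASURES) + [m for m in CONDITION_MEASURES
                                       if usable(m)]
    results = {}
    for i, meas in enumerate(measures):
        col = table.column(meas)
        try:
            res = st.permutation_pvalue(col, accuracy, n_perm=n_perm,
                                        seed=[seed, i])
            results[meas] = {"r": res.r, "p_perm": res.p_perm, "n": res.n}
        except st.DegenerateDataError as exc:
            raise st.DegenerateDataError(
                f"correlation stage, measure {meas}: {exc}") from exc
    fdr = st.fdr_correct([results[m]["p_perm"] for m in measures], q=q)
    for m, adj, rej in zip(measures, fdr.adjusted_p, fdr.rejected):
        results[m]["p_fdr"] = float(adj)
        results[m]["significant_fdr"] = bool(rej)
    return results


def _table_report(table: SubjectTable, accuracy: np.ndarray, n_perm: int,
                  q: float, seed: int, extra=None) -> dict:
    """The shared correlation/RMSE/descriptives/counts/groups report body."""
    ap = table.column("AP")
    pre = table.column("preAP")
    es = table.column("ES")

    correlations = _correlation_block(table, accuracy, n_perm, q, seed)
    es_ap = st.pearson(es, ap)

    high = accuracy >= 60.0
    n_excluded = int(np.sum(~high))
    if high.sum() >= 3 and np.ptp(ap[high]) > 0 and np.ptp(accuracy[high]) > 0:
        excl = st.permutation_pvalue(ap[high], accuracy[high], n_perm=n_perm,
                                     seed=[seed, 101])
        excl_block = {"n_excluded": n_excluded, "n_kept": int(high.sum()),
                      "r_ap_acc": excl.r, "p_perm": excl.p_perm}
    else:
        excl_block = {"n_excluded": n_excluded, "n_kept": int(high.sum()),
                      "r_ap_acc": None, "p_perm": None}

    groups = {}
    for criterion in ("coffee", "alcohol", "cigarette") + (
            ("sex", "age") if extra else ()):
        split = assign_groups(table, criterion,
                              extra=(extra or {}).get(criterion))
        ids = np.array(table.subject_ids)
        acc_a = accuracy[np.isin(ids, split.group_a_ids)]
        acc_b = accuracy[np.isin(ids, split.group_b_ids)]
        if len(acc_a) == 0 or len(acc_b) == 0:
            groups[criterion] = {"n_a": len(acc_a), "n_b": len(acc_b),
                                 "p": None, "method": "skipped: empty group"}
            continue
        test = st.ranksum_test(acc_a, acc_b)
        groups[criterion] = {
            "n_a": len(acc_a), "n_b": len(acc_b),
            "mean_a": float(acc_a.mean()), "mean_b": float(acc_b.mean()),
            "p": test.p, "method": test.method}

    return {
        "n_subjects": len(table),
        "provenance": table.provenance,
        "correlations": correlations,
        "r_es_ap": es_ap,
        "rmse_pre_task": st.rmse(pre, accuracy),
        "descriptives": {"accuracy": st.describe(accuracy),
                         "prediction": st.describe(ap)},
        "counts_below_60": {
            "accuracy": st.count_below(accuracy),
            "prediction": st.count_below(ap),
            "both": int(np.sum((accuracy < 60.0) & (ap < 60.0)))},
        "excluding_low_performers": excl_block,
        "group_comparisons": groups,
    }


def _write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    rows = [{"measure": m, **vals}
            for m, vals in report["correlations"].items()]
    pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)


def run_fixture_analysis(source="table2", n_perm: int = 2500, q: float = 0.1,
                         seed: int = 0, extra=None, out_dir=None) -> dict:
    """Full statistical report on a subject table.

    ``source`` is a builtin fixture name, a path, or a ready
    :class:`SubjectTable`. Returns the report dict; optionally writes
    ``report.json`` and ``correlations.csv`` to ``out_dir``.
    """
    table = source if isinstance(source, SubjectTable) \
        else load_subject_table(source)
    accuracy = table.column("ACC")
    if not np.all(np.isfinite(accuracy)):
        raise ValueError("table has missing ACC values; decode first")
    report = {
        "analysis": "table",
        "package_version": __version__,
        "config": {"n_perm": n_perm, "q": q, "seed": seed},
        **_table_report(table, accuracy, n_perm, q, seed, extra=extra),
    }
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def decode_recording(recording, band=(8.0, 30.0), window=(0.4, 2.4),
                     m_filters: int = 10, run_m_filters: int = 6,
                     k: int = 10, n_test: int = 3, stratified: bool = True,
                     seed: int = 0, run_wise: bool = True):
    """Band-pass, epoch, and cross-validate one recording.

    Returns ``(session_result, run_results)``; ``run_results`` is None when
    ``run_wise`` is false.
    """
    filtered = bandpass(recording, *band)
    epochs = epoch(filtered, window=window)
    session = cross_validated_accuracy(
        epochs, m_filters=m_filters, k=k, n_test=n_test,
        stratified=stratified, seed=seed)
    runs = None
    if run_wise:
        runs = run_wise_accuracy(
            epochs, m_filters=run_m_filters, k=k, n_test=n_test,
            stratified=stratified, seed=seed)
    return session, runs


def run_synthetic_experiment(config: PipelineConfig | None = None,
                             run_wise: bool = True,
                             out_dir=None) -> dict:
    """Generate a cohort, decode every subject, and analyze predictions.

    The decoded session accuracy replaces the table's ACC column; the report
    carries the same statistics as the table analysis plus the run-wise
    evolution series (correlation and RMSE of each stage's prediction with
    session accuracy, with permutation significance thresholds).
    """
    config = config or PipelineConfig()
    dec = config.decoding
    n_perm = config.stats["n_perm"]
    q = config.stats["q"]

    recordings, table = generate_cohort(config.cohort_config(),
                                        config.generator_config())
    session_rows, run_rows = [], []
    for rec, record in zip(recordings, table.records):
        session, runs = decode_recording(
            rec, band=tuple(dec["band"]), window=tuple(dec["window"]),
            m_filters=dec["m_filters"], run_m_filters=dec["run_m_filters"],
            k=dec["k"], n_test=dec["n_test"], stratified=dec["stratified"],
            seed=config.seed, run_wise=run_wise)
        record.accuracy = session.mean_accuracy
        record.accuracy_sd = session.accuracy_sd
        session_rows.append({"subject_id": record.subject_id,
                             **session.summary()})
        if runs:
            for ri, r in enumerate(runs):
                run_rows.append({"subject_id": record.subject_id,
                                 "run": ri + 1, **r.summary()})

    accuracy = table.column("ACC")
    report = {
        "analysis": "synthetic_experiment",
        "package_version": __version__,
        "config": {"seed": config.seed, "n_perm": n_perm, "q": q,
                   "decoding": dec, "generator": config.generator,
                   "cohort": {k: v for k, v in config.cohort.items()}},
        "n_subjects": len(table),
        "correlations": _correlation_block(table, accuracy, n_perm, q,
                                           config.seed),
        "rmse_pre_task": st.rmse(table.column("preAP"), accuracy),
        "descriptives": {"accuracy": st.describe(accuracy),
                         "prediction": st.describe(table.column("AP"))},
        "session_results": session_rows,
        "run_results": run_rows,
    }

    preds = {"pre-task": table.column("preAP")}
    run_matrix = table.run_prediction_matrix()
    for ri in range(run_matrix.shape[1]):
        preds[f"run{ri + 1}"] = run_matrix[:, ri]
    evo = st.evolution_analysis(preds, accuracy, n_perm=n_perm,
                                seed=config.seed)
    report["evolution"] = {
        "stages": evo.to_records(),
        "threshold_05": evo.threshold_05,
        "threshold_01": evo.threshold_01,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        pd.DataFrame(session_rows).to_csv(out / "cv_results.csv", index=False)
        if run_rows:
            pd.DataFrame(run_rows).to_csv(out / "cv_results_runwise.csv",
                                          index=False)
        pd.DataFrame(evo.to_records()).to_csv(out / "evolution.csv",
                                              index=False)
    return report
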