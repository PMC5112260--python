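"""End-to-end experiment orchestration.

Model taxonomy (the name determines inputs, protocol and training mode):

=================  ============================================================
``M-CD``           GMLVQ on the 4 cognitive scores (full cohort protocol)
``M-PSC`` etc.     GMLVQ on one 6-feature fMRI family (imaging cohort protocol)
``M-PSC+FGF``      two fMRI-input ensembles merged per test point
``M+-CD-PSC`` etc. cognitive-input GMLVQ with the fMRI family as privileged
                   information (ITML metric fusion)
``M+-CD-PSC+SGF``  two PI-guided ensembles merged per test point
=================  ============================================================

Every experiment runs repeated stratified splits; per split a
downsampling ensemble is trained and evaluated, member metric tensors and
balanced training errors are recorded for relevance analysis, and — for
graph families — the 2D-LDA edge-importance matrices of the frontal ROI
are kept per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .discriminant import TwoDLDA
from .evaluation import (
    DownsampledEnsembleClassifier,
    EvaluationReport,
    compare_models,
    macro_mae,
    make_splits,
    relative_median_reduction,
    summarize_mmae,
)
from .features import (
    assemble_feature_table,
    build_functional_basis,
    build_spatial_basis,
    compute_graph_matrix,
    compute_psc,
    reduce_graph,
)
from .gmlvq import GMLVQClassifier
from .privileged import PrivilegedGMLVQClassifier
from .simulate import PATIENT, SESSIONS, SyntheticCohort

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "summarize_tables",
           "MODEL_NAMES"]

FAMILIES = ("PSC", "SGF", "FGF")
MODEL_NAMES = (
    "M-CD", "M-PSC", "M-SGF", "M-FGF", "M-PSC+SGF", "M-PSC+FGF",
    "M+-CD-PSC", "M+-CD-SGF", "M+-CD-FGF", "M+-CD-PSC+SGF", "M+-CD-PSC+FGF",
)


@dataclass
class ExperimentConfig:
    model_name: str = "M-CD"
    n_splits: int = 50
    n_downsamples: int = 100
    seed: int = 0
    epochs: int = 300
    lr_prototype: float = 0.01
    lr_omega: float = 0.001
    # ITML percentile bounds (original / privileged space)
    a: float = 10.0
    b: float = 90.0
    a_star: float = 10.0
    b_star: float = 90.0
    tune_bounds: bool = False
    collect_relevance: bool = True

    def __post_init__(self):
        if self.model_name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.model_name!r}; expected one of {MODEL_NAMES}"
            )


@dataclass
class ExperimentResult:
    model_name: str
    report: EvaluationReport
    constituents: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model-name parsing
# ---------------------------------------------------------------------------

def _parse_model(name: str):
    """-> (input_kind, families, privileged) with input_kind in {CD, PD}."""
    if name == "M-CD":
        return "CD", [], False
    if name.startswith("M+-CD-"):
        fams = name[len("M+-CD-"):].split("+")
        return "CD", fams, True
    fams = name[len("M-"):].split("+")
    return "PD", fams, False


# ---------------------------------------------------------------------------
# feature preparation
# ---------------------------------------------------------------------------

class _GraphBank:
    """Per-(roi, session) graph matrices and spatial reductions for a cohort."""

    def __init__(self, cohort: SyntheticCohort, seed: int):
        self.subjects = sorted(cohort.imaging)
        self.graphs: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        self.coords: dict[str, np.ndarray] = {}
        self.kernels: dict[str, int] = {}
        from .features import default_n_kernels

        rois = sorted({roi for entry in cohort.imaging.values() for roi, _ in entry})
        for roi in rois:
            first = cohort.imaging[self.subjects[0]][(roi, SESSIONS[0])]
            self.coords[roi] = first.coords
            self.kernels[roi] = default_n_kernels(first.coords.shape[0])
        for roi in rois:
            for session in SESSIONS:
                bank = {}
                for subj in self.subjects:
                    ts = cohort.imaging[subj][(roi, session)]
                    bank[subj] = compute_graph_matrix(ts).G
                self.graphs[(roi, session)] = bank
        self.rois = rois
        self.seed = seed
        self._spatial_basis = {}
        self._spatial_reduced = {}

    def set_kernel_counts(self, counts: dict[str, int]):
        self.kernels.update(counts)

    def spatial_reduced(self, roi: str, session: str) -> dict[str, np.ndarray]:
        key = (roi, session)
        if key not in self._spatial_reduced:
            if roi not in self._spatial_basis:
                K = self.kernels[roi]
                self._spatial_basis[roi] = build_spatial_basis(
                    self.coords[roi], K, seed=self.seed, hemispheres=(K >= 8),
                )
            basis = self._spatial_basis[roi]
            self._spatial_reduced[key] = {
                s: reduce_graph(g, basis).X_tilde
                for s, g in self.graphs[key].items()
            }
        return self._spatial_reduced[key]

    def functional_reduced(self, roi: str, session: str, train_subjects
                           ) -> dict[str, np.ndarray]:
        bank = self.graphs[(roi, session)]
        train_graphs = [bank[s] for s in train_subjects if s in bank]
        basis = build_functional_basis(
            train_graphs, self.coords[roi], self.kernels[roi], seed=self.seed
        )
        return {s: reduce_graph(g, basis).X_tilde for s, g in bank.items()}


def _psc_table(cohort: SyntheticCohort) -> pd.DataFrame:
    values = {}
    for subj, entry in cohort.imaging.items():
        for (roi, session), ts in entry.items():
            values[(subj, roi, session)] = compute_psc(ts)
    return assemble_feature_table(values, "PSC",
                                  rois=_roi_columns(cohort))


def _roi_columns(cohort: SyntheticCohort):
    rois = sorted({roi for entry in cohort.imaging.values() for roi, _ in entry})
    return tuple(r.capitalize() for r in rois)


def _graph_family_table(bank: _GraphBank, family: str, train_subjects, y_by_subject,
                        cohort, importance_sink: dict | None):
    """Fit 2D-LDA per (roi, session) on training subjects, project everyone."""
    values = {}
    for roi in bank.rois:
        for session in SESSIONS:
            if family == "SGF":
                reduced = bank.spatial_reduced(roi, session)
            else:
                reduced = bank.functional_reduced(roi, session, train_subjects)
            train_ids = [s for s in train_subjects if s in reduced]
            Xtr = np.array([reduced[s] for s in train_ids])
            ytr = np.array([y_by_subject[s] for s in train_ids])
            model = TwoDLDA(positive_label=PATIENT)
            model.fit(Xtr, ytr)
            for subj, mat in reduced.items():
                values[(subj, roi, session)] = float(model.transform(mat[None])[0])
            if importance_sink is not None and roi == "frontal":
                importance_sink.setdefault((family, session), []).append(
                    model.importance_matrix_
                )
    return assemble_feature_table(values, family, rois=_roi_columns(cohort))


# ---------------------------------------------------------------------------
# single-ensemble experiments
# ---------------------------------------------------------------------------

def _evaluate_split(ens, X_test, y_test, patient_label=PATIENT):
    pred = ens.predict(X_test)
    tp = int(np.sum((y_test == patient_label) & (pred == patient_label)))
    fn = int(np.sum((y_test == patient_label) & (pred != patient_label)))
    tn = int(np.sum((y_test != patient_label) & (pred != patient_label)))
    fp = int(np.sum((y_test != patient_label) & (pred == patient_label)))
    return macro_mae(y_test, pred), {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def _run_single(cohort: SyntheticCohort, config: ExperimentConfig,
                families: list[str], input_kind: str, privileged: bool,
                shared_splits=None) -> tuple[EvaluationReport, object, list]:
    frame = cohort.cognitive_frame()
    subjects = frame.index.to_numpy()
    y_all = frame["group"].to_numpy()
    has_img = frame["has_imaging"].to_numpy()
    y_by_subject = dict(zip(subjects, y_all))
    X_cd = frame[list(frame.columns[1:5])].to_numpy(dtype=float)

    needs_graphs = any(f in ("SGF", "FGF") for f in families)
    bank = _GraphBank(cohort, seed=config.seed) if needs_graphs else None
    psc = _psc_table(cohort) if "PSC" in families else None

    if input_kind == "PD":
        keep = has_img
        sub_subjects = subjects[keep]
        sub_y = y_all[keep]
        protocol = "M-PD"
        plan = shared_splits or make_splits(
            sub_y, protocol=protocol, n_splits=config.n_splits, seed=config.seed
        )
    else:
        sub_subjects = subjects
        sub_y = y_all
        protocol = "M-CD"
        plan = shared_splits or make_splits(
            sub_y, protocol=protocol, has_imaging=has_img,
            n_splits=config.n_splits, seed=config.seed,
        )

    mmae_list, confusions = [], []
    member_lambdas, member_errors = [], []
    importance: dict = {}
    ss = np.random.SeedSequence([config.seed, 77])
    split_seeds = ss.generate_state(plan.n_splits) % (2**31)

    for k, (tr, te) in enumerate(plan.splits):
        train_subjects = list(sub_subjects[tr])
        sink = importance if (config.collect_relevance and needs_graphs) else None
        fam_tables = {}
        for fam in families:
            if fam == "PSC":
                fam_tables[fam] = psc
            else:
                fam_tables[fam] = _graph_family_table(
                    bank, fam, train_subjects, y_by_subject, cohort, sink
                )

        if input_kind == "PD":
            table = fam_tables[families[0]]
            X = table.loc[sub_subjects].to_numpy(dtype=float)
            base = GMLVQClassifier(
                epochs=config.epochs, lr_prototype=config.lr_prototype,
                lr_omega=config.lr_omega,
            )
            fit_kwargs = {}
        else:
            X = X_cd
            if privileged:
                table = fam_tables[families[0]]
                base = PrivilegedGMLVQClassifier(
                    a=config.a, b=config.b, a_star=config.a_star,
                    b_star=config.b_star, epochs=config.epochs,
                    lr_prototype=config.lr_prototype, lr_omega=config.lr_omega,
                )
            else:
                base = GMLVQClassifier(
                    epochs=config.epochs, lr_prototype=config.lr_prototype,
                    lr_omega=config.lr_omega,
                )
            fit_kwargs = {}

        X_train, y_train = X[tr], sub_y[tr]
        if input_kind == "CD" and privileged:
            img_positions = [p for p, s in enumerate(sub_subjects[tr])
                             if s in cohort.imaging]
            priv_ids = [sub_subjects[tr][p] for p in img_positions]
            Xp = table.loc[priv_ids].to_numpy(dtype=float)
            fit_kwargs = dict(X_privileged=Xp,
                              privileged_rows=np.array(img_positions))

        ens = DownsampledEnsembleClassifier(
            base_estimator=base, n_downsamples=config.n_downsamples,
            random_state=int(split_seeds[k]),
        )
        ens.fit(X_train, y_train, **fit_kwargs)
        mmae, conf = _evaluate_split(ens, X[te], sub_y[te])
        mmae_list.append(mmae)
        confusions.append(conf)
        if config.collect_relevance:
            member_lambdas.append([m.lambda_.copy() for m in ens.members_])
            member_errors.append(list(ens.member_train_errors_))
        last_ens = ens

    report = EvaluationReport(
        model_name="", mmae=np.array(mmae_list), confusions=confusions,
        member_lambdas=member_lambdas, member_errors=member_errors,
        importance=importance,
    )
    return report, plan, last_ens


def run_experiment(cohort: SyntheticCohort, config: ExperimentConfig
                   ) -> ExperimentResult:
    """Run the named experiment on a cohort and return its report.

    Hybrid names (two feature families) run both constituent experiments
    on identical splits and merge predictions per test point with the
    normalized-metric confidence rule.
    """
    input_kind, families, privileged = _parse_model(config.model_name)
    provenance = {"seed": config.seed, "n_splits": config.n_splits,
                  "n_downsamples": config.n_downsamples, "epochs": config.epochs}

    if config.model_name == "M-CD":
        report, plan, _ = _run_single(cohort, config, [], "CD", False)
        report.model_name = config.model_name
        return ExperimentResult(config.model_name, report, provenance=provenance)

    if len(families) == 1:
        report, plan, _ = _run_single(
            cohort, config, families, input_kind, privileged
        )
        report.model_name = config.model_name
        return ExperimentResult(config.model_name, report, provenance=provenance)

    # hybrid: run the two constituents on identical splits, combine per point
    return _run_hybrid(cohort, config, families, input_kind, privileged, provenance)


def _run_hybrid(cohort, config, families, input_kind, privileged, provenance):
    frame = cohort.cognitive_frame()
    subjects = frame.index.to_numpy()
    y_all = frame["group"].to_numpy()
    has_img = frame["has_imaging"].to_numpy()

    if input_kind == "PD":
        keep = has_img
        sub_subjects, sub_y = subjects[keep], y_all[keep]
        plan = make_splits(sub_y, protocol="M-PD",
                           n_splits=config.n_splits, seed=config.seed)
    else:
        sub_subjects, sub_y = subjects, y_all
        plan = make_splits(sub_y, protocol="M-CD", has_imaging=has_img,
                           n_splits=config.n_splits, seed=config.seed)

    sub_names = [(f"M+-CD-{fam}" if privileged else f"M-{fam}") for fam in families]
    acc = {name: {"mmae": [], "conf": [], "lams": [], "errs": []}
           for name in sub_names}
    mmae_list, confusions = [], []
    X_cd = frame[list(frame.columns[1:5])].to_numpy(dtype=float)

    for k, (tr, te) in enumerate(plan.splits):
        ens_pair, Xs = [], []
        one_plan = SplitPlanView(plan, k)
        if input_kind == "PD":
            Xs = _hybrid_inputs(cohort, config, families, sub_subjects, plan, k)
        else:
            Xs = [X_cd, X_cd]
        split_seed = int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0]
                         % (2**31))
        for fam, name in zip(families, sub_names):
            sub_cfg = replace(config, model_name=name, seed=split_seed)
            report, _, ens = _run_single(
                cohort, sub_cfg, [fam], input_kind, privileged,
                shared_splits=one_plan,
            )
            ens_pair.append(ens)
            a = acc[name]
            a["mmae"].append(report.mmae[0])
            a["conf"].append(report.confusions[0])
            if config.collect_relevance:
                a["lams"].append(report.member_lambdas[0])
                a["errs"].append(report.member_errors[0])
        pred = _combine_on_views(ens_pair, [x[te] for x in Xs])
        y_test = sub_y[te]
        tp = int(np.sum((y_test == PATIENT) & (pred == PATIENT)))
        fn = int(np.sum((y_test == PATIENT) & (pred != PATIENT)))
        tn = int(np.sum((y_test != PATIENT) & (pred != PATIENT)))
        fp = int(np.sum((y_test != PATIENT) & (pred == PATIENT)))
        mmae_list.append(macro_mae(y_test, pred))
        confusions.append({"tp": tp, "tn": tn, "fp": fp, "fn": fn})

    sub_results = {
        name: ExperimentResult(
            name,
            EvaluationReport(
                model_name=name, mmae=np.array(a["mmae"]), confusions=a["conf"],
                member_lambdas=a["lams"], member_errors=a["errs"],
            ),
        )
        for name, a in acc.items()
    }
    report = EvaluationReport(
        model_name=config.model_name, mmae=np.array(mmae_list),
        confusions=confusions,
    )
    return ExperimentResult(config.model_name, report,
                            constituents=sub_results, provenance=provenance)


class SplitPlanView:
    """A one-split view of a SplitPlan (shares indices, length 1)."""

    def __init__(self, plan, k):
        self.protocol = plan.protocol
        self.seed = plan.seed
        self.splits = [plan.splits[k]]
        self.n_splits = 1


def _hybrid_inputs(cohort, config, families, sub_subjects, plan, k):
    """Feature matrices (aligned to sub_subjects) per constituent family."""
    out = []
    frame = cohort.cognitive_frame()
    y_by_subject = dict(zip(frame.index, frame["group"]))
    bank = None
    for fam in families:
        if fam == "PSC":
            table = _psc_table(cohort)
        else:
            if bank is None:
                bank = _GraphBank(cohort, seed=config.seed)
            tr, _ = plan.splits[k]
            train_subjects = list(sub_subjects[tr])
            table = _graph_family_table(bank, fam, train_subjects,
                                        y_by_subject, cohort, None)
        out.append(table.loc[sub_subjects].to_numpy(dtype=float))
    return out


def _combine_on_views(ens_pair, X_views):
    """combine_two_classifiers where each ensemble sees its own features."""
    l1, d1 = ens_pair[0].vote_and_confidence(X_views[0])
    l2, d2 = ens_pair[1].vote_and_confidence(X_views[1])
    out = l1.copy()
    for i in range(len(l1)):
        if l1[i] != l2[i]:
            out[i] = l1[i] if d1[i] <= d2[i] else l2[i]
    return out


def summarize_tables(results: list[ExperimentResult],
                     baseline_name: str = "M-CD") -> pd.DataFrame:
    """Headline MMAE table with p-values and reductions vs. a baseline."""
    if not results:
        raise ValueError("no reports to summarize")
    n = {r.report.mmae.size for r in results}
    if len(n) > 1:
        raise ValueError(f"mismatched split counts across models: {sorted(n)}")
    baseline = next((r for r in results if r.model_name == baseline_name), None)
    rows = []
    for r in results:
        s = summarize_mmae(r.report.mmae)
        row = {"model": r.model_name, **s}
        if baseline is not None and r.model_name != baseline_name:
            row["p_value"] = compare_models(baseline.report.mmae, r.report.mmae)
            row["median_reduction_pct"] = relative_median_reduction(
                np.median(baseline.report.mmae), s["median"]
            )
        else:
            row["p_value"] = np.nan
            row["median_reduction_pct"] = np.nan
        rates = r.report.overall_rates
        row["TPR"] = rates["TPR"]
        row["TNR"] = rates["TNR"]
        rows.append(row)
    return pd.DataFrame(rows)
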