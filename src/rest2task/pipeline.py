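"""Orchestration of the experiment arms.

``run_rest_to_task`` runs the full comparison on one session: ICA is
trained separately on the concatenated rest windows (unsupervised, zero
labels) and on the concatenated imagery windows; motor components are
identified automatically in each decomposition; the resulting spatial
filters — plus the raw C3/C4 channels and fold-trained CSP filters — feed
band-power features into repeated cross-validated FDA classification.
Rest-window and imagery-window samples are disjoint by construction, and an
assertion enforces it: the rest-trained filters never saw a single imagery
sample.

``run_session_to_session`` instead trains ICA on session A's imagery data
and applies the unchanged filters to session B, the alternative
zero-training transfer the rest-to-task approach is compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CVResult, RestBaseline, cross_validate, cross_validate_extractor, zero_train_classify
from .decomposition import Decomposition, apply_filters, decompose_state, pattern_correlation
from .features import band_power, csp_features, csp_train, ica_features, monopolar_features
from .io import TrialSet, bandpass_array, state_segments
from .motor_ic import MotorICReport, Template, canonical_motor_template, select_motor_ics

METHODS = ("monopolar", "ica_imagery", "ica_rest", "csp")


@dataclass
class RunConfig:
    """Configuration of one evaluation run."""

    methods: tuple[str, ...] = METHODS
    n_components: int = 15
    cv_folds: int = 10
    cv_repetitions: int = 10
    band: tuple[float, float] = (8.0, 30.0)
    seed: int = 0


@dataclass
class RestToTaskResult:
    accuracies: dict[str, CVResult]
    report: pd.DataFrame
    dec_rest: Decomposition
    dec_imagery: Decomposition
    selection_rest: MotorICReport
    selection_imagery: MotorICReport

    def to_json(self) -> str:
        payload = {
            "methods": {
                m: {"mean_accuracy_pct": r.mean, "std_pct": r.std}
                for m, r in self.accuracies.items()
            },
            "selected_rest": {"left": int(self.selection_rest.selected_left),
                              "right": int(self.selection_rest.selected_right)},
            "selected_imagery": {"left": int(self.selection_imagery.selected_left),
                                 "right": int(self.selection_imagery.selected_right)},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _decompose_and_select(
    ts: TrialSet, state: str, template: Template, cfg: RunConfig
) -> tuple[Decomposition, MotorICReport]:
    X = state_segments(ts, state)
    dec = decompose_state(X, cfg.n_components, seed=cfg.seed, state_tag=state)
    tc = apply_filters(dec, X)
    tc.fs = ts.fs
    report = select_motor_ics(dec, tc, template, ts.montage)
    return dec, report


def _feature_table(
    ts: TrialSet,
    dec: Decomposition | None,
    report: MotorICReport | None,
    method: str,
    band: tuple[float, float],
) -> np.ndarray:
    segs = ts.state_trials("imagery")
    rows = []
    for seg in segs:
        if method == "monopolar":
            fv = monopolar_features(seg, ts.channel_labels, ts.fs, band)
        else:
            fv = ica_features(seg, dec, report.selected_left, report.selected_right,
                              ts.fs, band)
        rows.append(fv.as_array())
    return np.stack(rows)


def run_rest_to_task(
    ts: TrialSet, template: Template | None = None, cfg: RunConfig | None = None
) -> RestToTaskResult:
    """Full four-arm comparison on one session.

    Requires both state windows; the montage is taken from the trial set.
    If no group template is supplied, the canonical hand-area template is
    used for motor-component identification.
    """
    cfg = cfg or RunConfig()
    for state in ("rest", "imagery"):
        if state not in ts.windows:
            raise ValueError(f"session lacks the '{state}' window")
    # strict state separation: rest training data must not overlap imagery
    r = ts.window_samples("rest")
    m = ts.window_samples("imagery")
    assert r[1] <= m[0] or m[1] <= r[0], "rest and imagery windows overlap"
    if ts.montage is None:
        raise ValueError("session needs montage coordinates for dipole fitting")
    if template is None:
        template = canonical_motor_template(ts.channel_labels, ts.montage)

    dec_rest, sel_rest = _decompose_and_select(ts, "rest", template, cfg)
    dec_img, sel_img = _decompose_and_select(ts, "imagery", template, cfg)

    accuracies: dict[str, CVResult] = {}
    for method in cfg.methods:
        if method == "monopolar":
            X = _feature_table(ts, None, None, "monopolar", cfg.band)
            accuracies[method] = cross_validate(
                X, ts.labels, cfg.cv_folds, cfg.cv_repetitions, cfg.seed)
        elif method == "ica_rest":
            X = _feature_table(ts, dec_rest, sel_rest, "ica", cfg.band)
            accuracies[method] = cross_validate(
                X, ts.labels, cfg.cv_folds, cfg.cv_repetitions, cfg.seed)
        elif method == "ica_imagery":
            X = _feature_table(ts, dec_img, sel_img, "ica", cfg.band)
            accuracies[method] = cross_validate(
                X, ts.labels, cfg.cv_folds, cfg.cv_repetitions, cfg.seed)
        elif method == "csp":
            accuracies[method] = _csp_cv(ts, cfg)
        else:
            raise ValueError(f"unknown method {method!r}")

    report = pd.DataFrame(
        {
            "method": list(accuracies),
            "filter_source": [
                {"monopolar": "none", "ica_imagery": "imagery", "ica_rest": "rest",
                 "csp": "imagery (per fold)"}[m_]
                for m_ in accuracies
            ],
            "accuracy_pct": [accuracies[m_].mean for m_ in accuracies],
            "std_pct": [accuracies[m_].std for m_ in accuracies],
        }
    )
    return RestToTaskResult(accuracies, report, dec_rest, dec_img, sel_rest, sel_img)


def _csp_cv(ts: TrialSet, cfg: RunConfig) -> CVResult:
    """CSP arm: filters trained only inside each training fold, on
    band-filtered imagery segments."""
    segs = ts.state_trials("imagery")
    filtered = bandpass_array(segs, ts.fs, *cfg.band)
    classes = np.unique(ts.labels)

    def factory(train_trials: np.ndarray, train_labels: np.ndarray):
        model = csp_train(train_trials[train_labels == classes[0]],
                          train_trials[train_labels == classes[1]])
        return lambda seg: csp_features(seg, model, ts.fs, cfg.band).as_array()

    return cross_validate_extractor(
        filtered, ts.labels, factory, cfg.cv_folds, cfg.cv_repetitions, cfg.seed)


def run_session_to_session(
    ts_a: TrialSet, ts_b: TrialSet, template: Template | None = None,
    cfg: RunConfig | None = None,
) -> tuple[CVResult, MotorICReport]:
    """Classify session B with ICA filters trained on session A's imagery data.

    Both sessions must share the channel layout.  Returns session B's
    cross-validated accuracy and session A's motor-component report.
    """
    cfg = cfg or RunConfig()
    if ts_a.channel_labels != ts_b.channel_labels:
        raise ValueError("sessions have different channel layouts")
    if template is None:
        template = canonical_motor_template(ts_a.channel_labels, ts_a.montage)
    dec_a, sel_a = _decompose_and_select(ts_a, "imagery", template, cfg)
    X = np.stack([
        ica_features(seg, dec_a, sel_a.selected_left, sel_a.selected_right,
                     ts_b.fs, cfg.band).as_array()
        for seg in ts_b.state_trials("imagery")
    ])
    return (
        cross_validate(X, ts_b.labels, cfg.cv_folds, cfg.cv_repetitions, cfg.seed),
        sel_a,
    )


def cross_state_similarity(
    dec_rest: Decomposition,
    dec_imagery: Decomposition,
    sel_rest: MotorICReport,
    sel_imagery: MotorICReport,
) -> pd.DataFrame:
    """Pattern and filter correlations of the selected motor components
    between the rest-trained and imagery-trained decompositions."""
    rows = []
    for side in ("left", "right"):
        i = getattr(sel_rest, f"selected_{side}")
        j = getattr(sel_imagery, f"selected_{side}")
        rows.append({
            "side": side,
            "pattern_r": pattern_correlation(dec_rest.patterns[:, i],
                                             dec_imagery.patterns[:, j]),
            "filter_r": pattern_correlation(dec_rest.filters[i],
                                            dec_imagery.filters[j]),
        })
    return pd.DataFrame(rows)


def rest_baseline(
    ts: TrialSet, dec: Decomposition, report: MotorICReport,
    band: tuple[float, float] = (8.0, 30.0),
) -> RestBaseline:
    """Mean resting band power of the selected motor components."""
    segs = ts.state_trials("rest")
    pl, pr = [], []
    for seg in segs:
        tc = apply_filters(dec, seg, [report.selected_left, report.selected_right])
        p = band_power(tc.data, ts.fs, band)
        pl.append(p[0])
        pr.append(p[1])
    return RestBaseline(float(np.mean(pl)), float(np.mean(pr)))


def zero_training_accuracy(
    ts: TrialSet, dec: Decomposition, report: MotorICReport,
    weighted: bool = True, band: tuple[float, float] = (8.0, 30.0),
) -> float:
    """Accuracy (%) of the zero-training rule over all trials.

    With ``weighted=False`` the baseline is set to (1, 1): the plain sign
    rule, provided for comparison with the baseline-weighted rule.
    """
    base = rest_baseline(ts, dec, report, band) if weighted else RestBaseline(1.0, 1.0)
    hits = 0
    for seg, lab in zip(ts.state_trials("imagery"), ts.labels):
        tc = apply_filters(dec, seg, [report.selected_left, report.selected_right])
        p = band_power(tc.data, ts.fs, band)
        u = zero_train_classify(p[0], p[1], base)
        hits += (u == 1) == (lab == "left")
    return 100.0 * hits / ts.n_trials


def save_report(result: RestToTaskResult, out_dir: str | Path) -> None:
    """Write the accuracy table (TSV) and run summary (JSON), byte-stable
    for a fixed config + seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "accuracies.tsv", sep="\t", index=False,
                         float_format="%.6f")
    (out / "summary.json").write_text(result.to_json() + "\n")
    result.selection_rest.table.to_csv(out / "motor_ics_rest.tsv", sep="\t",
                                       float_format="%.6f")
    result.selection_imagery.table.to_csv(out / "motor_ics_imagery.tsv", sep="\t",
                                          float_format="%.6f")
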