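"""End-to-end orchestration: recordings to subject features to diagnosis.

``run_subject`` takes a reading recording (silence measures), a word
recording with vowel annotations (PVI measures), assembles the subject
feature row, and evaluates both diagnostic index models.  ``run_cohort``
classifies a feature table and optionally refits the discriminant model
after screening.  Reports carry provenance (inputs, parameters, a
parameter hash, and the package version) sufficient to re-run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import ValidationError
from .lexical_stress import read_vowel_annotations, stress_profile, word_pvi
from .signal_core import (
    DEFAULT_FLOOR_DB,
    DEFAULT_HOP_S,
    DEFAULT_WINDOW_S,
    read_wav,
)
from .silence_analysis import SilenceConfig, analyze_waveform, read_exclusions_csv
from .stats_models import (
    GROUP_CODES,
    MODEL1_COEFFICIENTS,
    MODEL2_COEFFICIENTS,
    collinearity_screen,
    duration_index,
    fit_dfa,
    mahalanobis_screen,
    silence_duration_index,
)

__all__ = ["PipelineConfig", "run_subject", "run_cohort", "classify_features"]

MODEL_NAMES = ("duration", "silence-duration")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of a subject-level run."""

    window_s: float = DEFAULT_WINDOW_S
    hop_s: float = DEFAULT_HOP_S
    floor_db: float = DEFAULT_FLOOR_DB
    silence: SilenceConfig = field(default_factory=SilenceConfig)
    tier: str = "vowels"
    db_offset: float = 96.0
    model1_coefficients: Mapping[str, float] = field(default_factory=lambda: dict(MODEL1_COEFFICIENTS))
    model2_coefficients: Mapping[str, float] = field(default_factory=lambda: dict(MODEL2_COEFFICIENTS))

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        silence = data.pop("silence", None)
        cfg = cls(**data) if silence is None else cls(silence=SilenceConfig(**silence), **data)
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        out["silence"] = asdict(self.silence)
        return out


def _param_hash(params: Mapping) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_subject(
    reading_wav,
    words_wav,
    annotations,
    cfg: PipelineConfig = PipelineConfig(),
    *,
    subject_id: str = "subject",
    exclusions_csv=None,
) -> dict:
    """Process one subject end to end; returns a JSON-serialisable report."""
    reading = read_wav(reading_wav)
    words = read_wav(words_wav)
    exclusions = read_exclusions_csv(exclusions_csv) if exclusions_csv else ()

    try:
        metrics, silences = analyze_waveform(
            reading,
            cfg.silence,
            window_s=cfg.window_s,
            hop_s=cfg.hop_s,
            floor_db=cfg.floor_db,
            exclusions=exclusions,
        )
    except Exception as exc:
        raise type(exc)(f"silence stage: {exc}") from exc

    try:
        tokens = read_vowel_annotations(annotations, tier=cfg.tier)
        records = [
            word_pvi(
                words,
                tok,
                window_s=cfg.window_s,
                hop_s=cfg.hop_s,
                floor_db=cfg.floor_db,
                db_offset=cfg.db_offset,
            )
            for tok in tokens
        ]
        profile = stress_profile(records)
    except Exception as exc:
        raise type(exc)(f"lexical-stress stage: {exc}") from exc

    if profile.median_pvi_dur_ws_abs is None or profile.median_pvi_dur_sw_abs is None:
        raise ValidationError("lexical-stress stage: need at least one WS and one SW token")
    if metrics.mad_s is None:
        raise ValidationError("silence stage: no silences detected; Model 1 features undefined")

    features = {
        "subject_id": subject_id,
        "group": "",
        "arcsin_pst": metrics.arcsin_pst,
        "mad_silence_s": metrics.mad_s,
        "median_silence_s": metrics.median_s,
        "pvi_dur_ws": profile.median_pvi_dur_ws_abs,
        "pvi_dur_sw": profile.median_pvi_dur_sw_abs,
        "pvi_int_ws": profile.median_pvi_int_ws_abs,
        "pvi_int_sw": profile.median_pvi_int_sw_abs,
    }
    model2 = duration_index(
        features["pvi_dur_ws"], features["pvi_dur_sw"], cfg.model2_coefficients
    )
    model1 = silence_duration_index(
        features["arcsin_pst"],
        features["mad_silence_s"],
        features["pvi_dur_ws"],
        cfg.model1_coefficients,
    )
    params = cfg.to_dict()
    return {
        "features": features,
        "silence_metrics": metrics.to_dict(),
        "stress_profile": profile.to_dict(),
        "word_pvi": [r.to_dict() for r in records],
        "classification": {
            "duration": {"index": model2.index, "class_code": model2.class_code, "label": model2.label},
            "silence-duration": {"index": model1.index, "class_code": model1.class_code, "label": model1.label},
        },
        "provenance": {
            "reading_wav": str(reading_wav),
            "words_wav": str(words_wav),
            "annotations": str(annotations),
            "exclusions_csv": None if exclusions_csv is None else str(exclusions_csv),
            "parameters": params,
            "parameter_hash": _param_hash(params),
            "version": __version__,
        },
    }


def classify_features(
    features: pd.DataFrame,
    model: str = "duration",
    coefficients: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-row diagnostic classification of a feature table."""
    if model not in MODEL_NAMES:
        raise ValidationError(f"model must be one of {MODEL_NAMES}, got {model!r}")
    required = (
        ("pvi_dur_ws", "pvi_dur_sw")
        if model == "duration"
        else ("arcsin_pst", "mad_silence_s", "pvi_dur_ws")
    )
    missing = [c for c in required if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table is missing column(s) {missing}")
    rows = []
    for row in features.itertuples(index=False):
        if model == "duration":
            res = duration_index(
                float(row.pvi_dur_ws),
                float(row.pvi_dur_sw),
                coefficients or MODEL2_COEFFICIENTS,
            )
        else:
            res = silence_duration_index(
                float(row.arcsin_pst),
                float(row.mad_silence_s),
                float(row.pvi_dur_ws),
                coefficients or MODEL1_COEFFICIENTS,
            )
        rows.append({"index": res.index, "class_code": res.class_code, "label": res.label})
    out = features[["subject_id", "group"]].copy() if "subject_id" in features else pd.DataFrame(index=features.index)
    return pd.concat([out.reset_index(drop=True), pd.DataFrame(rows)], axis=1)


def run_cohort(
    features: pd.DataFrame,
    model: str = "duration",
    *,
    fit: bool = False,
    predictors: Sequence[str] | None = None,
    screen: bool = False,
    alpha: float = 0.001,
    use_refit_coefficients: bool = False,
) -> dict:
    """Classify a cohort and optionally refit the discriminant model.

    Agreement is the proportion of labelled lvPPA/nfvPPA subjects whose
    model class matches their group label; control subjects are never
    classified into the agreement summary.
    """
    if "group" not in features.columns:
        raise ValidationError("feature table is missing the 'group' column")
    patients = features[features["group"].isin(GROUP_CODES)].reset_index(drop=True)
    report: dict = {"n_total": int(len(features)), "n_patients": int(len(patients))}

    fit_result = None
    screen_result = None
    if fit:
        if patients["group"].nunique() < 2:
            raise ValidationError(
                "fitting requires both lvPPA and nfvPPA groups in the feature table"
            )
        preds = list(predictors) if predictors else ["arcsin_pst", "mad_silence_s", "pvi_dur_ws", "pvi_dur_sw"]
        if screen:
            screen_result = collinearity_screen(patients, preds)
            preds = list(screen_result.retained)
            d2, flags, critical = mahalanobis_screen(patients[preds].to_numpy(), alpha=alpha)
            report["mahalanobis"] = {
                "critical": critical,
                "n_flagged": int(flags.sum()),
                "flagged_subjects": patients.loc[flags, "subject_id"].tolist(),
            }
            report["collinearity"] = {
                "retained": list(screen_result.retained),
                "excluded": list(screen_result.excluded),
            }
        fit_result = fit_dfa(patients, "group", preds)
        report["fit"] = fit_result.to_dict()

    coefficients = None
    if use_refit_coefficients:
        if fit_result is None:
            raise ValidationError("use_refit_coefficients requires fit=True")
        coefficients = fit_result.coefficients()
        classified = _classify_with_fit(patients, fit_result)
    else:
        classified = classify_features(patients, model=model)

    expected = patients["group"].map(GROUP_CODES)
    agree = (classified["class_code"].to_numpy() == expected.to_numpy())
    report["classification"] = classified.to_dict(orient="records")
    report["agreement"] = float(agree.mean()) if len(agree) else float("nan")
    report["n_agree"] = int(agree.sum())
    report["model"] = "refit" if use_refit_coefficients else model
    return report


def _classify_with_fit(patients: pd.DataFrame, fit_result) -> pd.DataFrame:
    from .stats_models import _classify  # internal rounding rule

    rows = []
    for _, row in patients.iterrows():
        index = fit_result.constant + sum(
            b * float(row[name]) for name, b in zip(fit_result.predictors, fit_result.b)
        )
        res = _classify(index)
        rows.append({"index": res.index, "class_code": res.class_code, "label": res.label})
    out = patients[["subject_id", "group"]].reset_index(drop=True)
    return pd.concat([out, pd.DataFrame(rows)], axis=1)
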