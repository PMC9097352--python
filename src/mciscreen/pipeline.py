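"""End-to-end run: extract -> deboilerplate -> cohort -> features -> fit -> evaluate.

Every run writes its resolved configuration first, then stage artifacts, then
a manifest with SHA-256 hashes of inputs and outputs plus the seed — rerunning
with the same inputs and seed reproduces byte-identical CSV artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .boilerplate import BoilerplateFlagger, drop_boilerplate
from .cohort import (
    DEFAULT_DEPARTMENTS, LOOKBACK_DAYS, apply_exclusions, load_code_config,
    select_notes, split_cohort,
)
from .dictionary import load_dictionary
from .evaluation import DEFAULT_CUTOFFS, cutoff_sweep, roc_auc
from .features import FeatureBuilder, label_from_score, split_features_labels
from .model import LassoScreeningClassifier, predict_probability, save_model
from .synthetic_corpus import patients_from_frame
from .text_matcher import extract_corpus_mentions, read_notes_ndjson, write_mentions_csv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    dictionary_path: str
    notes_path: str
    patients_path: str
    out_dir: str
    code_config_path: str | None = None
    departments: tuple[str, ...] = DEFAULT_DEPARTMENTS
    lookback_days: int = LOOKBACK_DAYS
    train_fraction: float = 0.6
    folds: int = 10
    seed: int = 0
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    min_other_patients: int = 1
    count_mode: str = "presence"
    text_exclusions: bool = True  # drop patients with patient_exclusion CUI mentions

    def validate(self) -> None:
        for name in ("dictionary_path", "notes_path", "patients_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError(f"config: {name} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True), encoding="utf-8"
    )

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    dictionary = stage("dictionary")(lambda: load_dictionary(cfg.dictionary_path))
    notes = stage("read_notes")(lambda: read_notes_ndjson(cfg.notes_path))
    patients_frame = stage("read_patients")(lambda: pd.read_csv(cfg.patients_path))
    patients, index_dates = stage("read_patients")(
        lambda: patients_from_frame(patients_frame)
    )
    by_pid = {p.patient_id: p for p in patients}

    def _window_notes():
        kept = []
        for n in notes:
            idx = index_dates.get(n.patient_id)
            if idx is None:
                continue
            kept.extend(select_notes([n], idx, cfg.departments, cfg.lookback_days))
        return kept

    window_notes = stage("select_notes")(_window_notes)

    mentions = stage("extract")(lambda: extract_corpus_mentions(window_notes, dictionary))
    flagger = BoilerplateFlagger(min_other_patients=cfg.min_other_patients)
    flagged = stage("deboilerplate")(lambda: flagger.fit(mentions).transform(mentions))
    write_mentions_csv(flagged, out / "mentions.csv")

    code_config = stage("cohort")(lambda: load_code_config(cfg.code_config_path))
    retained, tally = stage("cohort")(
        lambda: apply_exclusions(patients, index_dates, code_config,
                                 notes=notes, lookback_days=cfg.lookback_days)
    )
    if cfg.text_exclusions:
        excl_cuis = set(dictionary.patient_exclusion_cuis())
        flagged_pids = {
            m.patient_id for m in drop_boilerplate(flagged) if m.cui in excl_cuis
        }
        n_before = len(retained)
        retained = [p for p in retained if p.patient_id not in flagged_pids]
        tally.add("text_exclusion_cuis", n_before - len(retained))
        tally.n_retained = len(retained)
    pd.DataFrame(tally.steps, columns=["step", "removed"]).to_csv(
        out / "exclusion_tally.csv", index=False
    )

    cohort_ids = [p.patient_id for p in retained]
    cohort_index = {pid: index_dates[pid] for pid in cohort_ids}
    labels = {}
    for p in retained:
        usable = [s for s in p.scores if s.instrument in ("MMSE", "MoCA")]
        if usable:
            labels[p.patient_id] = label_from_score(usable[0])

    split = split_cohort(sorted(labels), cfg.train_fraction, seed=cfg.seed)
    pd.DataFrame(sorted(split.items()), columns=["patient_id", "split"]).to_csv(
        out / "split.csv", index=False
    )

    builder = FeatureBuilder(
        dictionary, count_mode=cfg.count_mode, allow_missing_sum_components=True
    ).fit()
    frame = stage("features")(
        lambda: builder.transform(flagged, by_pid, cohort_index, labels)
    )
    frame.to_csv(out / "features.csv")

    X, y = split_features_labels(frame)
    is_train = frame.index.map(lambda pid: split[pid] == "train").to_numpy()
    model = stage("fit")(
        lambda: LassoScreeningClassifier(folds=cfg.folds, random_state=cfg.seed).fit(
            X[is_train], y[is_train]
        )
    )
    save_model(model, out / "model.json")
    model.coefficient_table().to_csv(out / "coefficients.csv", index=False)

    metrics: dict = {"train": {}, "validation": {}}
    for name, mask in (("train", is_train), ("validation", ~is_train)):
        probs = predict_probability(model, X[mask])
        sweep = cutoff_sweep(probs, y[mask], cfg.cutoffs)
        sweep.insert(0, "cohort", name)
        sweep.to_csv(out / f"sweep_{name}.csv", index=False)
        roc = roc_auc(probs, y[mask], seed=cfg.seed)
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(
            out / f"roc_{name}.csv", index=False
        )
        metrics[name] = {
            "n": int(mask.sum()),
            "prevalence": float(y[mask].mean()),
            "auc": roc.auc,
            "auc_ci": [roc.ci_low, roc.ci_high],
        }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1), encoding="utf-8")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {
            name: _sha256(Path(getattr(cfg, name)))
            for name in ("dictionary_path", "notes_path", "patients_path")
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json")
            and p.name != "manifest.json"  # run_config.yaml echoes absolute paths
        },
        "n_mentions": len(flagged),
        "n_boilerplate": sum(m.boilerplate for m in flagged),
        "exclusion_tally": tally.steps,
        "n_cohort": len(labels),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
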