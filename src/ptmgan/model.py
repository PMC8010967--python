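"""High-level modelling interface.

:class:`PtmClassifier` bundles the whole pipeline — encoding, correlation
screening, optional GAN balancing, random forest — behind a fit-once object,
and :class:`PtmResults` carries the cross-validated and independent-test
estimates with a ``summary()`` table, in the spirit of statsmodels model /
results pairs.

Example
-------
>>> from ptmgan.fixtures import FixtureSpec, fixture_dataset
>>> from ptmgan.model import PtmClassifier
>>> ds, struct = fixture_dataset(FixtureSpec({"A": 60, "B": 60}, seed=1))
>>> res = PtmClassifier(ds, structure=struct).fit(seed=1)
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .classify_eval import (
    PipelineOptions,
    SplitPlan,
    aggregate_importance,
    confusion,
    make_split,
    metrics_report,
    run_pipeline_fold,
)
from .fragments import Dataset, extract_fragments, filter_classes, merge_labels, \
    read_fasta, read_sites_tsv, remove_redundant
from .encoders import StructureTable


class PtmClassifier:
    """Multi-class lysine-modification site classifier.

    Parameters
    ----------
    dataset : Dataset
        Single-label fragment dataset (see :mod:`ptmgan.fragments`).
    structure : StructureTable, optional
        Per-residue structural channels; omitted -> sequence-only encoding.
    options : PipelineOptions, optional
        Encoding/filter/augmentation/forest settings.
    """

    def __init__(
        self,
        dataset: Dataset,
        structure: Optional[StructureTable] = None,
        options: Optional[PipelineOptions] = None,
    ):
        self.dataset = dataset
        self.options = options or PipelineOptions()
        if structure is not None:
            self.options = replace(self.options, structure=structure)

    @classmethod
    def from_files(
        cls,
        fasta_path,
        sites_path,
        structure_path=None,
        xi: int = 8,
        identity_threshold: float = 0.40,
        min_count: int = 500,
        options: Optional[PipelineOptions] = None,
    ) -> "PtmClassifier":
        """Build straight from FASTA + site-annotation (+ structure) files."""
        proteins = read_fasta(fasta_path)
        sites = read_sites_tsv(sites_path)
        frags = extract_fragments(proteins, sites, xi=xi)
        frags = remove_redundant(frags, threshold=identity_threshold)
        frags = merge_labels(frags)
        dataset = filter_classes(frags, min_count=min_count)
        structure = (
            StructureTable.from_tsv(structure_path) if structure_path else None
        )
        return cls(dataset, structure=structure, options=options)

    def fit(self, seed: int = 0) -> "PtmResults":
        """Run stratified CV on the training 4/5 and an independent 1/5 test.

        Every fold refits the whole pipeline on its training rows only; CV
        predictions are pooled over folds into one confusion matrix.
        """
        y = self.dataset.y
        K = self.dataset.class_set.n_classes
        opts = replace(self.options, seed=seed)
        split = make_split(y, seed=seed, n_folds=opts.n_folds)

        cv_true, cv_pred = [], []
        cv_scores = []
        for fit_idx, val_idx in split.folds:
            fold = run_pipeline_fold(self.dataset, fit_idx, val_idx, opts)
            cv_true.append(fold.y_true)
            cv_pred.append(fold.y_pred)
            cv_scores.append(fold.scores)
        cv_true = np.concatenate(cv_true)
        cv_pred = np.concatenate(cv_pred)
        cv_scores = np.vstack(cv_scores)
        cv_cm = confusion(cv_true, cv_pred, K)

        test_fold = run_pipeline_fold(self.dataset, split.train_idx, split.test_idx, opts)
        per_scheme, ranked = aggregate_importance(test_fold.rf, test_fold.provenance)
        return PtmResults(
            model=self,
            split=split,
            cv_confusion=cv_cm,
            cv_scores=cv_scores,
            cv_true=cv_true,
            test_confusion=test_fold.cm,
            test_scores=test_fold.scores,
            test_true=test_fold.y_true,
            importance_by_scheme=per_scheme,
            importance_ranked=ranked,
            n_features_used=len(test_fold.mask_kept),
        )


@dataclass
class PtmResults:
    """Fitted-pipeline estimates: confusion matrices, metrics, importances."""

    model: PtmClassifier
    split: SplitPlan
    cv_confusion: np.ndarray
    cv_scores: np.ndarray
    cv_true: np.ndarray
    test_confusion: np.ndarray
    test_scores: np.ndarray
    test_true: np.ndarray
    importance_by_scheme: pd.Series
    importance_ranked: pd.DataFrame
    n_features_used: int

    @property
    def cv_report(self) -> dict:
        return metrics_report(self.cv_confusion, self.cv_scores, self.cv_true)

    @property
    def test_report(self) -> dict:
        return metrics_report(self.test_confusion, self.test_scores, self.test_true)

    def to_json(self, path) -> None:
        def strip(report):
            return {k: v for k, v in report.items() if k != "per_class"} | {
                "per_class": report["per_class"].reset_index().to_dict("records")
            }

        payload = {
            "seed": self.split.seed,
            "n_features_used": self.n_features_used,
            "class_names": list(self.model.dataset.class_set.names),
            "cross_validation": strip(self.cv_report),
            "independent_test": strip(self.test_report),
            "cv_confusion": self.cv_confusion.tolist(),
            "test_confusion": self.test_confusion.tolist(),
            "importance_by_scheme": self.importance_by_scheme.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def summary(self) -> str:
        """Human-readable overview of both evaluations."""
        names = self.model.dataset.class_set.names
        cv, te = self.cv_report, self.test_report
        lines = [
            "Lysine-modification multiclass classification",
            "=" * 54,
            f"classes: {', '.join(names)}",
            f"samples: {len(self.model.dataset)}   "
            f"features used: {self.n_features_used}   seed: {self.split.seed}",
            f"augmentation: {self.model.options.augment or 'none'}",
            "",
            f"{'':24s}{'Acc':>8s}{'MCC':>8s}{'CEN':>8s}{'E':>8s}",
        ]
        for label, rep in (("cross-validation", cv), ("independent test", te)):
            lines.append(
                f"{label:24s}{rep['Acc']:8.4f}{rep['MCC']:8.4f}"
                f"{rep['CEN']:8.4f}{rep['E']:8.4f}"
            )
        lines.append("")
        lines.append("independent test, per class:")
        pc = te["per_class"].copy()
        pc.index = list(names)
        lines.append(pc.round(4).to_string())
        lines.append("")
        lines.append("cumulative importance by scheme:")
        lines.append(self.importance_by_scheme.round(4).to_string())
        return "\n".join(lines)
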