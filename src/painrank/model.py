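"""Model/Results facade for the full prioritization analysis.

:class:`PainGeneClassifier` is built from data — a synthetic cohort, a
prepared :class:`~painrank.features.FeatureMatrix`, or a plain
DataFrame — and owns the leakage-safe feature pipeline (stratified
70/30 split; GO TF-IDF/PCA and min-max scaling fitted on training rows
only; correlation filtering measured on training rows). Its ``fit()``
trains the weighted soft-voting ensemble (optionally the stacking
variant), runs the configured cross-validation, scores every gene, and
returns a :class:`PainGeneResults` carrying the estimates, their fold
variability, diagnostics, and a ``summary()`` table.

Typical use::

    cohort = simulate.generate(simulate.SimConfig(seed=7))
    model = PainGeneClassifier.from_cohort(cohort, seed=7)
    res = model.fit()
    print(res.summary())
    res.enrich([cohort.validation_set])
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import features as feat
from .enrichment import PainScoreTable, rank_genes, validate_against_sets
from .metrics import confusion_from_predictions, metric_set
from .topology import compute_topology

__all__ = ["PainGeneClassifier", "PainGeneResults"]


class PainGeneClassifier:
    """Pain-gene prioritization model over an engineered feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Scaled gene x feature matrix with 0/1 labels (1 = pain class).
    train_genes, val_genes : index-like, optional
        Pre-computed stratified split; made from ``seed`` if omitted.
    specs : list of BaseLearnerSpec, optional
        Base learners; the four-member default if omitted.
    weight_multiset : tuple
        Voting weights to permute over the members (default (4, 2, 1, 3)).
    seed : int
        Master seed for the split, folds, and every learner.
    """

    def __init__(self, features: feat.FeatureMatrix, train_genes=None,
                 val_genes=None, specs=None,
                 weight_multiset=ens.DEFAULT_WEIGHT_MULTISET,
                 seed: int = ens.DEFAULT_SEED):
        self.features = features
        self.specs = specs
        self.weight_multiset = tuple(weight_multiset)
        self.seed = seed
        if train_genes is None or val_genes is None:
            train_genes, val_genes = feat.split_stratified(
                features.y, train_fraction=0.7, seed=seed
            )
        self.train_genes = pd.Index(train_genes)
        self.val_genes = pd.Index(val_genes)

    # -- constructors --------------------------------------------------

    @classmethod
    def from_cohort(cls, cohort, seed: int | None = None, specs=None,
                    weight_multiset=ens.DEFAULT_WEIGHT_MULTISET,
                    train_fraction: float = 0.7, n_go_components: int = 2,
                    corr_threshold: float = 0.75,
                    topology_profiles: pd.DataFrame | None = None):
        """Build the model from a synthetic (or equally structured) cohort.

        Runs the whole feature pipeline; the fitted GO featurizer and
        scaler are exposed as ``go_featurizer_`` and ``scaler_`` for
        inspection, and both see training rows only.
        """
        seed = cohort.config.seed if seed is None else seed
        labels = cohort.labels.astype(int)
        topo = topology_profiles if topology_profiles is not None \
            else compute_topology(cohort.graph)

        train, val = feat.split_stratified(labels, train_fraction, seed)

        go = feat.GoFeaturizer(n_components=n_go_components)
        go.fit(cohort.go_annotations, sorted(train))
        go_features = go.transform(cohort.go_annotations, sorted(labels.index))

        fm = feat.assemble_features(cohort.table, cohort.meta, topo,
                                    labels, go_features)
        scaler = feat.SymmetricMinMaxScaler().fit(fm.X.loc[train])
        X = scaler.transform(fm.X)
        kept, dropped = feat.correlation_filter(X.loc[train], corr_threshold)
        X = X[kept.columns]
        zero_var = [c for c in X.columns if X.loc[train, c].nunique() == 1]
        X = X.drop(columns=zero_var)
        fm = feat.FeatureMatrix(
            X, fm.y,
            {**fm.provenance,
             "dropped_features": dropped + zero_var,
             "corr_threshold": corr_threshold},
        )
        model = cls(fm, train, val, specs, weight_multiset, seed)
        model.go_featurizer_ = go
        model.scaler_ = scaler
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       **kwargs):
        """Build from an already numeric DataFrame with a label column."""
        y = df[label_col].astype(int)
        X = df.drop(columns=[label_col]).astype(float)
        return cls(feat.FeatureMatrix(X, y), **kwargs)

    # -- fitting -------------------------------------------------------

    def fit(self, method: str = "voting", cv_folds: int = 10,
            select_features: bool = False, oof_folds: int = 5,
            tune_weights: bool = True) -> "PainGeneResults":
        """Train the ensemble; returns a results object.

        ``cv_folds=0`` skips cross-validation (the held-out validation
        metrics are always computed). ``select_features`` runs
        attribution-guided backward elimination on the training rows
        first and restricts the model to the winning subset.
        """
        fm = self.features
        Xtr = fm.X.loc[self.train_genes]
        ytr = fm.y.loc[self.train_genes].to_numpy()

        selected = list(fm.X.columns)
        trajectory = None
        if select_features:
            selected, trajectory = ens.backward_eliminate(
                Xtr, ytr, self._factory(method, oof_folds, tune_weights=False),
                folds=min(5, cv_folds) if cv_folds else 5, seed=self.seed,
            )
            Xtr = Xtr[selected]

        model = self._factory(method, oof_folds, tune_weights)()
        model.fit(Xtr.to_numpy(), ytr)
        weights = getattr(model, "weights_", None)

        cv = None
        if cv_folds:
            # CV re-fits the ensemble per fold with the searched weights
            # held fixed; re-running the permutation search inside every
            # fold would multiply cost without changing the assessment
            if method == "voting":
                w = weights.weights if weights else self.weight_multiset
                factory = lambda: ens.VotingEnsemble(
                    self.specs, w, tune_weights=False, seed=self.seed)
            else:
                factory = self._factory(method, oof_folds, tune_weights=False)
            cv = ens.cross_validate(Xtr.to_numpy(), ytr, factory,
                                    folds=cv_folds, seed=self.seed)

        Xval = fm.X.loc[self.val_genes, selected]
        yval = fm.y.loc[self.val_genes].to_numpy()
        val_proba = model.predict_proba(Xval.to_numpy())[:, 1]
        val_metrics = metric_set(confusion_from_predictions(
            yval, (val_proba >= 0.5).astype(int)))

        all_proba = model.predict_proba(fm.X[selected].to_numpy())[:, 1]
        scores = rank_genes(dict(zip(fm.X.index, all_proba)))

        contrib = model.attributions(Xval.to_numpy()) \
            if hasattr(model, "attributions") else None
        importance = None
        if contrib is not None:
            importance = pd.Series(
                np.abs(contrib).mean(axis=0), index=selected,
                name="mean_abs_attribution").sort_values(ascending=False)

        return PainGeneResults(
            model=self, method=method, ensemble=model, weights=weights,
            selected_features=selected, elimination_trajectory=trajectory,
            cv=cv, val_metrics=val_metrics, scores=scores,
            feature_importance=importance,
        )

    def _factory(self, method, oof_folds, tune_weights):
        if method == "voting":
            return lambda: ens.VotingEnsemble(
                self.specs, self.weight_multiset, tune_weights=tune_weights,
                oof_folds=oof_folds, seed=self.seed)
        if method == "stacking":
            return lambda: ens.StackingEnsemble(
                self.specs, oof_folds=oof_folds, seed=self.seed)
        raise ValueError(f"method must be 'voting' or 'stacking', got {method!r}")


class PainGeneResults:
    """Fitted estimates, diagnostics and the genome-wide pain ranking."""

    def __init__(self, model, method, ensemble, weights, selected_features,
                 elimination_trajectory, cv, val_metrics, scores,
                 feature_importance):
        self.model = model
        self.method = method
        self.ensemble = ensemble
        self.weights = weights
        self.selected_features = selected_features
        self.elimination_trajectory = elimination_trajectory
        self.cv = cv
        self.val_metrics = val_metrics
        self.scores: PainScoreTable = scores
        self.feature_importance = feature_importance

    @property
    def training_positives(self) -> frozenset:
        y = self.model.features.y
        tr = self.model.train_genes
        return frozenset(y.loc[tr].index[y.loc[tr] == 1])

    def enrich(self, sets, n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
        """Validate the ranking against gene sets, with and without
        removal of training-labelled positives."""
        seed = self.model.seed if seed is None else seed
        return validate_against_sets(self.scores, sets,
                                     self.training_positives, n_perm, seed)

    def summary(self) -> str:
        fm = self.model.features
        lines = [
            "Pain-gene prioritization results",
            "=" * 58,
            f"method:            {self.method} ensemble",
            f"genes:             {len(fm.genes)}  "
            f"(P={int(fm.y.sum())}, NP={int((1 - fm.y).sum())})",
            f"features used:     {len(self.selected_features)}",
            f"train / val genes: {len(self.model.train_genes)} / "
            f"{len(self.model.val_genes)}",
            f"seed:              {self.model.seed}",
        ]
        if self.weights is not None:
            members = [s.name for s in (self.ensemble.specs_)]
            lines.append("voting weights:    "
                         + ", ".join(f"{m}={w:g}" for m, w in
                                     zip(members, self.weights.weights)))
        lines.append("-" * 58)
        if self.cv is not None:
            m, s = self.cv.mean(), self.cv.sd()
            lines.append(f"cross-validation ({len(self.cv.folds)} folds, "
                         "mean +/- SD):")
            for k in ("mcc", "gm", "ba", "f1"):
                lines.append(f"  {k.upper():<4} {m.as_dict()[k]:7.4f} +/- "
                             f"{s.as_dict()[k]:.4f}")
        lines.append("held-out validation split:")
        for k, v in self.val_metrics.as_dict().items():
            lines.append(f"  {k.upper():<4} {v:7.4f}")
        top = self.scores.table.head(5)
        lines.append("-" * 58)
        lines.append("top-ranked genes (pain score):")
        for _, row in top.iterrows():
            lines.append(f"  {int(row['rank']):>4}  {row['gene_id']}"
                         f"  {row['pain_score']:.4f}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------

    def model_card(self) -> dict:
        card = {
            "schema_version": 1,
            "method": self.method,
            "seed": self.model.seed,
            "weight_multiset": list(self.model.weight_multiset),
            "weights": list(self.weights.weights) if self.weights else None,
            "members": [s.name for s in self.ensemble.specs_],
            "specs": [asdict(s) for s in self.ensemble.specs_],
            "selected_features": list(self.selected_features),
            "n_train": int(len(self.model.train_genes)),
            "n_val": int(len(self.model.val_genes)),
            "val_metrics": self.val_metrics.as_dict(),
        }
        if self.cv is not None:
            card["cv_mean"] = self.cv.mean().as_dict()
            card["cv_sd"] = self.cv.sd().as_dict()
            card["cv_folds"] = [f.as_dict() for f in self.cv.folds]
        return card

    def save_model(self, path: str | Path) -> None:
        """Persist the fitted ensemble in a single versioned archive."""
        import joblib

        joblib.dump({
            "schema_version": 1,
            "method": self.method,
            "ensemble": self.ensemble,
            "weights": self.weights,
            "selected_features": list(self.selected_features),
            "seed": self.model.seed,
        }, path)

    @staticmethod
    def load_model(path: str | Path) -> dict:
        """Load a persisted ensemble archive (see :meth:`save_model`)."""
        import joblib

        payload = joblib.load(path)
        if payload.get("schema_version") != 1:
            raise ValueError(
                f"unsupported model archive schema: {payload.get('schema_version')!r}"
            )
        return payload

    def save(self, outdir: str | Path) -> None:
        """Write the pain-score table and model card."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_tsv(outdir / "pain_scores.tsv")
        with open(outdir / "model_card.json", "w") as fh:
            json.dump(self.model_card(), fh, indent=1, sort_keys=True)
        if self.feature_importance is not None:
            self.feature_importance.to_csv(outdir / "feature_importance.tsv",
                                           sep="\t", header=True)
        if self.elimination_trajectory is not None:
            traj = self.elimination_trajectory.copy()
            traj["features"] = traj["features"].map(",".join)
            traj.to_csv(outdir / "elimination_trajectory.tsv", sep="\t",
                        index=False)
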