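"""End-to-end training and prediction workflow.

Wires the stages together in the order the method prescribes: stratified
80/20 train/validation split -> tri-segment deep and shallow encodings ->
F-score ranking and stepwise selection on the shallow features (training
split only; the deep features bypass selection) -> deep network on the
deep features, classifier bank on the selected shallow features -> bank
ranking -> incremental soft-vote combination search -> final ensemble.

The result is a self-contained :class:`TrainedPipeline` bundle that can
featurize, predict and evaluate new FASTA data, and can be persisted with
joblib.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from supenh.bank import ShallowBankConfig, rank_shallow_bank, train_shallow_bank
from supenh.deep import DeepModelConfig, build_deep_model, train_deep_model
from supenh.embedding import EmbeddingMatrix, encode_deep_dataset
from supenh.ensemble import CombinationSearchResult, SoftVotingEnsemble, combination_search
from supenh.metrics import MetricsReport, evaluate_scores
from supenh.models import TrainedModel
from supenh.selection import FScoreRanking, SelectionSweep, apply_selection, fscore_rank, stepwise_select
from supenh.sequences import SequenceDataset, holdout_split
from supenh.shallow import EIIPTable, encode_shallow_dataset
from supenh.synthetic import default_embedding_fixtures

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a training run."""

    ks: tuple[int, ...] = (4, 5, 6)
    dim: int = 64
    embedding_paths: tuple[str, ...] | None = None  # word2vec text files, else fixtures
    embedding_seed: int = 0
    eiip_convention: str = "sum"
    selection_step: int = 10
    train_fraction: float = 0.8
    top_n_shallow: int = 4  # how many ranked bank members enter the search
    deep: DeepModelConfig = field(default_factory=DeepModelConfig)
    bank: ShallowBankConfig = field(default_factory=ShallowBankConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-seed every stochastic stage coherently."""
        return replace(
            self,
            seed=seed,
            embedding_seed=seed,
            deep=replace(self.deep, seed=seed),
            bank=replace(self.bank, seed=seed),
        )


def load_embeddings(config: PipelineConfig) -> list[EmbeddingMatrix]:
    if config.embedding_paths:
        embs = [EmbeddingMatrix.load_word2vec(p) for p in config.embedding_paths]
        ks = tuple(e.k for e in embs)
        if ks != tuple(config.ks):
            raise ValueError(f"loaded embeddings have k={ks}, config expects {config.ks}")
        return embs
    return default_embedding_fixtures(config.ks, config.dim, config.embedding_seed)


def featurize_dataset(
    dataset: SequenceDataset,
    embeddings: list[EmbeddingMatrix],
    eiip: EIIPTable,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """(deep matrix, shallow matrix, skipped ids), rows aligned on record id."""
    X_deep, skipped_deep = encode_deep_dataset(dataset, embeddings)
    X_shallow, skipped_shallow = encode_shallow_dataset(dataset, eiip)
    skipped = sorted(set(skipped_deep) | set(skipped_shallow))
    keep = [i for i in X_deep.index if i in set(X_shallow.index)]
    return X_deep.loc[keep], X_shallow.loc[keep], skipped


@dataclass
class TrainedPipeline:
    """A trained ensemble plus every fitted transformation it depends on."""

    config: PipelineConfig
    embeddings: list[EmbeddingMatrix]
    eiip: EIIPTable
    ranking: FScoreRanking
    sweep: SelectionSweep
    chosen_dim: int
    selected_features: tuple[str, ...]
    deep_member: TrainedModel
    bank: dict[str, TrainedModel]
    bank_ranking: list[tuple[str, float, float]]
    search: CombinationSearchResult
    ensemble: SoftVotingEnsemble

    def featurize(self, dataset: SequenceDataset) -> tuple[dict[str, pd.DataFrame], list[str]]:
        """Per-space feature matrices for new data, selection applied."""
        X_deep, X_shallow, skipped = featurize_dataset(dataset, self.embeddings, self.eiip)
        X_selected = X_shallow.loc[:, list(self.selected_features)]
        return {"deep": X_deep, "shallow": X_selected}, skipped

    def predict(self, dataset: SequenceDataset) -> pd.DataFrame:
        """Per-record (id, probability, label) for all encodable records."""
        features, skipped = self.featurize(dataset)
        proba, labels = self.ensemble.predict(features)
        if skipped:
            logger.warning("%d records skipped as unencodable: %s...", len(skipped), skipped[:3])
        return pd.DataFrame(
            {"id": features["deep"].index, "probability": proba, "label": labels}
        )

    def evaluate(self, dataset: SequenceDataset) -> MetricsReport:
        """Headline metrics of the ensemble on a labeled dataset."""
        features, _ = self.featurize(dataset)
        label_map = {rec.id: rec.label for rec in dataset}
        y_true = np.array([label_map[i] for i in features["deep"].index], dtype=int)
        proba, _ = self.ensemble.predict(features)
        return evaluate_scores(y_true, proba)

    def member_reports(self, dataset: SequenceDataset) -> dict[str, MetricsReport]:
        """Per-member metrics on a labeled dataset (keys are member kinds)."""
        features, _ = self.featurize(dataset)
        label_map = {rec.id: rec.label for rec in dataset}
        y_true = np.array([label_map[i] for i in features["deep"].index], dtype=int)
        return {
            m.kind: evaluate_scores(y_true, m.predict_proba(features[m.space]))
            for m in self.ensemble.members
        }

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "TrainedPipeline":
        return joblib.load(Path(path))


def train_pipeline(dataset: SequenceDataset, config: PipelineConfig | None = None) -> TrainedPipeline:
    """Train the full soft-voting ensemble on a labeled dataset."""
    config = config or PipelineConfig()
    train_ds, val_ds = holdout_split(dataset, config.train_fraction, config.seed)
    embeddings = load_embeddings(config)
    eiip = EIIPTable(convention=config.eiip_convention)

    Xd_tr, Xs_tr, skipped_tr = featurize_dataset(train_ds, embeddings, eiip)
    Xd_va, Xs_va, skipped_va = featurize_dataset(val_ds, embeddings, eiip)
    if skipped_tr or skipped_va:
        logger.warning("skipped %d unencodable records", len(skipped_tr) + len(skipped_va))
    lab_tr = {r.id: r.label for r in train_ds}
    lab_va = {r.id: r.label for r in val_ds}
    y_tr = np.array([lab_tr[i] for i in Xs_tr.index], dtype=int)
    y_va = np.array([lab_va[i] for i in Xs_va.index], dtype=int)

    # shallow feature selection, fitted on the training split only
    ranking = fscore_rank(Xs_tr, y_tr)
    sweep = stepwise_select(
        Xs_tr, y_tr, ranking, step=config.selection_step, split_seed=config.seed
    )
    chosen = sweep.chosen_dim
    Xsel_tr = apply_selection(Xs_tr, ranking, chosen)
    Xsel_va = apply_selection(Xs_va, ranking, chosen)
    logger.info("feature selection kept %d of %d shallow features", chosen, Xs_tr.shape[1])

    deep_model = build_deep_model(config.deep, n_features=Xd_tr.shape[1], token_dim=config.dim)
    deep_member = train_deep_model(deep_model, Xd_tr, y_tr, Xd_va, y_va)

    bank = train_shallow_bank(Xsel_tr, y_tr, config.bank)
    bank_order = rank_shallow_bank(bank, Xsel_va, y_va)
    top = [bank[name] for name, _, _ in bank_order[: config.top_n_shallow]]

    features_val = {"deep": Xd_va, "shallow": Xsel_va}
    search = combination_search(deep_member, top, features_val, y_va)
    ensemble = SoftVotingEnsemble(search.best_members)

    return TrainedPipeline(
        config=config,
        embeddings=embeddings,
        eiip=eiip,
        ranking=ranking,
        sweep=sweep,
        chosen_dim=chosen,
        selected_features=tuple(Xsel_tr.columns),
        deep_member=deep_member,
        bank=bank,
        bank_ranking=bank_order,
        search=search,
        ensemble=ensemble,
    )
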