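"""Greedy forward feature selection with correlation pruning.

Candidate scales enter a pool C (the top-k of the AUC ranking).  The
loop pops the highest-ranked candidate f, builds the integrative-profile
classifier from the current selection S plus f, and measures its 5-fold
balanced-CV AUC.  f is accepted iff the AUC improves on the S-only
baseline by more than epsilon (an empty S scores 0.5, chance level); on
acceptance, every remaining candidate whose per-residue values correlate
with f at |r| >= rho is pruned from C.  The loop ends when C is empty.

One CV plan (folds and negative draws) is drawn once per run and reused
for every candidate evaluation, so consecutive AUC comparisons are
paired rather than re-randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from pssmpp.aaindex import PropertyRanking, PropertyScale
from pssmpp.encoders import WindowSpec, build_feature_matrix
from pssmpp.model_eval import build_cv_plan, cross_validate_features
from pssmpp.pssm import PSSMProfile, ResidueSample, residues_and_labels


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant input."""


@dataclass
class SelectionConfig:
    """Knobs of the selection workflow.

    preselect_k : size of the AUC-preselected candidate pool (default 20).
    corr_threshold : absolute Pearson bound rho; candidates at |r| >= rho
        with an accepted feature are pruned (default 0.8).
    improvement_epsilon : minimum CV-AUC gain to accept (default 0.0).
    cv_folds, cv_grouping, window_size, encoder, seed : evaluation protocol.
    """

    preselect_k: int = 20
    corr_threshold: float = 0.8
    improvement_epsilon: float = 0.0
    cv_folds: int = 5
    cv_grouping: str = "chain"
    window_size: int = 17
    encoder: str = "pssmpp"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")
        if self.preselect_k < 1:
            raise ValueError("preselect_k must be >= 1")
        if self.encoder not in ("pssmpp", "pp"):
            raise ValueError("selection encoder must be 'pssmpp' or 'pp'")

    @classmethod
    def from_yaml(cls, path) -> "SelectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class TraceEntry:
    accession: str
    auc_without: float
    auc_with: float
    accepted: bool
    pruned: list[str] = field(default_factory=list)


@dataclass
class SelectionState:
    """Outcome of the greedy loop: remaining C, selected S, full audit trail."""

    candidates_C: list[str]
    selected_S: list[str]
    trace: list[TraceEntry] = field(default_factory=list)


def pearson_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation of two per-sample value vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must be equal-length with at least 2 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantInputError("correlation undefined for a constant input")
    return float(stats.pearsonr(a, b).statistic)


def greedy_select(
    ranking: PropertyRanking,
    scales: Sequence[PropertyScale],
    samples: Sequence[ResidueSample],
    profiles: dict[str, PSSMProfile],
    config: SelectionConfig | None = None,
) -> SelectionState:
    """Run the iterative selection workflow; returns the final state.

    Correlations are computed over per-residue assigned values across the
    dataset's samples (equivalently, amino-acid-composition-weighted
    correlation of the 20-value scales).
    """
    config = config or SelectionConfig()
    if not ranking.entries:
        return SelectionState(candidates_C=[], selected_S=[], trace=[])
    by_acc = {s.accession: s for s in scales}
    missing = [a for a in ranking.top(config.preselect_k) if a not in by_acc]
    if missing:
        raise ValueError(f"ranking references unknown scales: {missing}")

    residues, _ = residues_and_labels(samples, profiles)
    per_residue = {
        acc: by_acc[acc].values_for_sequence(residues)
        for acc in ranking.top(config.preselect_k)
    }

    spec = WindowSpec(config.window_size)
    plan = build_cv_plan(samples, folds=config.cv_folds, seed=config.seed,
                         grouping=config.cv_grouping)

    # Encode once over the whole candidate pool; a candidate subset is a
    # column selection of this matrix (the RBF kernel is invariant to
    # feature order, so this matches encoding the subset directly).
    pool = ranking.top(config.preselect_k)
    pool_fm = build_feature_matrix(config.encoder, profiles, samples, spec,
                                   [by_acc[a] for a in pool])
    col_idx = {acc: [i for i, c in enumerate(pool_fm.columns)
                     if c.endswith(f".prop.{acc}")] for acc in pool}
    term_idx = [i for i, c in enumerate(pool_fm.columns) if c.endswith(".term")]

    def cv_auc(selected: list[str]) -> float:
        cols = sorted(term_idx + [i for a in selected for i in col_idx[a]])
        result = cross_validate_features(pool_fm.values[:, cols], samples, plan)
        return float(result.pooled.AUC)

    C = list(ranking.top(config.preselect_k))
    S: list[str] = []
    trace: list[TraceEntry] = []
    baseline = 0.5  # empty model: chance-level AUC
    while C:
        f = C.pop(0)
        auc_without = baseline
        auc_with = cv_auc(S + [f])
        accepted = auc_with - auc_without > config.improvement_epsilon
        pruned: list[str] = []
        if accepted:
            S.append(f)
            baseline = auc_with
            survivors = []
            for c in C:
                try:
                    r = pearson_correlation(per_residue[c], per_residue[f])
                except ConstantInputError:
                    r = 0.0
                if abs(r) >= config.corr_threshold:
                    pruned.append(c)
                else:
                    survivors.append(c)
            C = survivors
        trace.append(TraceEntry(
            accession=f,
            auc_without=auc_without,
            auc_with=auc_with,
            accepted=accepted,
            pruned=pruned,
        ))
    return SelectionState(candidates_C=C, selected_S=S, trace=trace)


def write_selection_report(state: SelectionState, trace_path, selected_path) -> None:
    """TSV trace plus the final selected-accession list."""
    with open(trace_path, "w") as fh:
        fh.write("accession\tauc_without\tauc_with\taccepted\tpruned\n")
        for e in state.trace:
            fh.write(f"{e.accession}\t{e.auc_without:.6f}\t{e.auc_with:.6f}\t"
                     f"{int(e.accepted)}\t{','.join(e.pruned)}\n")
    with open(selected_path, "w") as fh:
        for acc in state.selected_S:
            fh.write(acc + "\n")
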