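"""Phase-balanced sequential feature selection (SFS).

Each run draws a 50% bootstrap of the circadian-significant genes,
shortlists the 25 most significant per 4-h phase bin (up to 150
candidates), seeds the feature set with one random shortlist gene, and
then alternates:

* forward step — pick an under-represented phase bin (random among
  ties), trial-insert every remaining shortlist gene of that bin, and
  commit the insertion with the lowest fivefold-CV mean absolute
  circular error;
* reverse step (once the set reaches 8 genes) — trial-remove every gene
  except the newest addition and greedily commit removals that strictly
  lower the CV error, never shrinking below 3 genes.

The run stops at 40 genes, shortlist exhaustion, or an evaluation
budget, and returns the best state visited (an anytime algorithm).  CV
folds are fixed per run so every cost comparison is paired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_scaling import ExpressionMatrix
from .nn import CyclicMLPRegressor, Hyperparams, cv_mae, time_stratified_folds
from .rhythmicity import N_PHASE_BINS, RhythmicityTable

MAX_FEATURES = 40
MIN_FEATURES = 3
REVERSE_AT = 8


class BudgetExhausted(Exception):
    """Internal control flow: the evaluation budget ran out."""


@dataclass
class FeatureSet:
    """Outcome of one SFS run: an ordered gene list and its CV score."""

    gene_ids: list
    cv_mae: float
    bin_counts: list
    run_seed: int
    iteration_log: list = field(default_factory=list)
    n_evaluations: int = 0

    def write_log(self, path) -> None:
        """Line-oriented JSON audit log, one record per evaluation."""
        with open(path, "w") as fh:
            for action, gene, mae, size in self.iteration_log:
                fh.write(json.dumps(
                    {"action": action, "gene": gene, "cv_mae": mae, "set_size": size}
                ) + "\n")


def bootstrap_universe(t: RhythmicityTable, frac: float = 0.5, seed: int = 0) -> list:
    """Seeded uniform sample without replacement of ``floor(frac*n)`` genes."""
    genes = sorted(t.gene_ids)
    if not genes:
        raise ValueError("empty rhythmicity table")
    n_take = int(np.floor(frac * len(genes)))
    if frac >= 1.0:
        return genes
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genes), size=n_take, replace=False)
    return [genes[i] for i in sorted(idx)]


def build_shortlist(universe, t: RhythmicityTable, top_n: int = 25) -> list:
    """Top ``top_n`` genes per phase bin by ascending Q within the universe.

    Bins with fewer candidates contribute all they have; Q ties break by
    gene id so the shortlist is deterministic.
    """
    sub = t.table.loc[[g for g in universe if g in t.table.index]]
    shortlist = []
    for b in range(N_PHASE_BINS):
        members = sub[sub["phase_bin"] == b]
        ranked = members.assign(_g=members.index.astype(str)).sort_values(
            ["q_value", "_g"], kind="mergesort"
        )
        shortlist.extend(ranked.index[:top_n].tolist())
    return shortlist


def select_underrepresented_bin(bin_counts, available_bins, rng) -> int:
    """Bin with minimal count among bins that still have candidates.

    Random (seeded) choice among ties; when the globally minimal bin is
    exhausted the next least-represented available bin is used.
    """
    avail = sorted(available_bins)
    if not avail:
        raise BudgetExhausted("all shortlist candidates exhausted")
    counts = np.asarray(bin_counts)
    min_count = min(counts[b] for b in avail)
    ties = [b for b in avail if counts[b] == min_count]
    return int(rng.choice(ties))


def _default_factory(hp: Hyperparams):
    def make():
        return CyclicMLPRegressor(
            hidden_sizes=hp.hidden_sizes, learning_rate=hp.learning_rate,
            batch_size=hp.batch_size, l2_factor=hp.l2_factor,
            epochs=hp.epochs, seed=hp.seed, n_restarts=hp.n_restarts,
        )
    return make


def run_sfs(m: ExpressionMatrix, t: RhythmicityTable, budget: int, seed: int,
            hp: Hyperparams | None = None, estimator_factory=None,
            bootstrap_frac: float = 0.5, top_n: int = 25, cv_k: int = 5) -> FeatureSet:
    """One SFS run over a scaled training matrix.

    Parameters
    ----------
    m : ExpressionMatrix
        Scaled training matrix with time labels in the metadata.
    t : RhythmicityTable
        Prior already filtered to circadian-significant genes.
    budget : int
        Maximum number of CV-cost evaluations (each trial insertion or
        removal costs one).  Must cover initialisation (1 evaluation).
    seed : int
        Drives the bootstrap, the initial gene, bin tie-breaks, CV folds
        and the wrapped estimator.
    hp : Hyperparams, optional
        Network knobs when the default estimator is used.
    estimator_factory : callable, optional
        Zero-argument callable returning an unfitted minutes-scale
        regressor; overrides ``hp``.
    """
    if budget < 1:
        raise ValueError("budget too small to complete initialisation")
    hp = hp or Hyperparams(seed=seed)
    factory = estimator_factory or _default_factory(hp)
    rng = np.random.default_rng(seed)

    universe = bootstrap_universe(t, frac=bootstrap_frac, seed=seed)
    shortlist = build_shortlist(universe, t, top_n=top_n)
    if not shortlist:
        raise ValueError("empty shortlist")
    bin_of = t.phase_bin_of().to_dict()
    y = m.times_min()
    folds = time_stratified_folds(y, k=min(cv_k, len(np.unique(y))), seed=seed)

    log: list = []
    state = {"evals": 0}

    def evaluate(genes, action, gene_label):
        if state["evals"] >= budget:
            raise BudgetExhausted
        state["evals"] += 1
        score = cv_mae(m.X(genes), y, factory, folds=folds)
        log.append((action, gene_label, score, len(genes)))
        return score

    def bin_counts(genes):
        counts = [0] * N_PHASE_BINS
        for g in genes:
            counts[bin_of[g]] += 1
        return counts

    best_genes: list = []
    best_mae = np.inf

    def checkpoint(genes, mae):
        nonlocal best_genes, best_mae
        if mae < best_mae:
            best_mae = mae
            best_genes = list(genes)

    init_gene = shortlist[int(rng.integers(len(shortlist)))]
    current = [init_gene]
    remaining = [g for g in shortlist if g != init_gene]
    try:
        current_mae = evaluate(current, "init", init_gene)
        checkpoint(current, current_mae)
        while len(current) < MAX_FEATURES:
            avail_bins = {bin_of[g] for g in remaining}
            if not avail_bins:
                break
            b = select_underrepresented_bin(bin_counts(current), avail_bins, rng)
            candidates = sorted(g for g in remaining if bin_of[g] == b)
            best_cand, best_cand_mae = None, np.inf
            try:
                for g in candidates:
                    score = evaluate(current + [g], "insert_trial", g)
                    if score < best_cand_mae:
                        best_cand, best_cand_mae = g, score
            finally:
                if best_cand is not None:
                    current = current + [best_cand]
                    remaining.remove(best_cand)
                    current_mae = best_cand_mae
                    log.append(("insert_commit", best_cand, current_mae, len(current)))
                    checkpoint(current, current_mae)
            newest = current[-1]
            # reverse elimination once the set is large enough
            while len(current) >= REVERSE_AT:
                best_rm, best_rm_mae = None, current_mae
                for g in list(current):
                    if g == newest:
                        continue
                    trial = [x for x in current if x != g]
                    score = evaluate(trial, "remove_trial", g)
                    if score < best_rm_mae:
                        best_rm, best_rm_mae = g, score
                if best_rm is None or len(current) - 1 < MIN_FEATURES:
                    break
                current = [x for x in current if x != best_rm]
                current_mae = best_rm_mae
                log.append(("remove_commit", best_rm, current_mae, len(current)))
                checkpoint(current, current_mae)
    except BudgetExhausted:
        pass

    if not best_genes:
        raise ValueError("budget too small to complete initialisation")
    return FeatureSet(
        gene_ids=best_genes,
        cv_mae=float(best_mae),
        bin_counts=bin_counts(best_genes),
        run_seed=seed,
        iteration_log=log,
        n_evaluations=state["evals"],
    )
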