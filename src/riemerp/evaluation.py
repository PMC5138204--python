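"""Accuracy-vs-averaging evaluation of oddball command decoding.

The protocol: cross-validate over selection blocks; per fold and per
averaging depth ``k`` (1..5), average groups of ``k`` same-code epochs,
fit the class prototypes and both classifiers on the training blocks, and
decide one command per selection round on the held-out blocks.  Results
are aggregated to mean +/- SD command accuracy (percent) per classifier
and depth, with a two-sided Wilcoxon rank-sum p-value comparing the two
classifiers' per-fold accuracies at each depth.  Chance is 100/K percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .classifiers import (
    MDM,
    SWLDA,
    command_select,
    decimate_epochs,
    swlda_command_select,
)
from .preprocessing import NONTARGET, TARGET, EpochSet, SuperTrialCovariance

__all__ = [
    "AccuracyTable",
    "GrandAverage",
    "average_erps",
    "evaluate",
    "ranksum_compare",
    "chance_level",
    "grand_average",
]


@dataclass
class AccuracyTable:
    """Command accuracy (%) per classifier and averaging depth.

    ``table`` has one row per (classifier, k) with mean and SD across
    cross-validation folds; ``p_values`` maps k to the rank-sum p of the
    MDM-vs-SWLDA per-fold accuracy comparison.  ``fold_accuracies`` keeps
    the raw per-fold percentages, ``metadata`` the protocol provenance
    (seed, folds, aggregation convention).
    """

    table: pd.DataFrame
    p_values: dict[int, float]
    chance_percent: float
    fold_accuracies: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class GrandAverage:
    """Per-class mean ERP waveform with per-sample standard-error bands."""

    target_mean: np.ndarray  # (n_channels, n_times)
    target_se: np.ndarray
    nontarget_mean: np.ndarray
    nontarget_se: np.ndarray
    fs: float
    channel_names: list[str]
    n_target: int
    n_nontarget: int


def average_erps(epochs: EpochSet, k: int) -> EpochSet:
    """Average consecutive disjoint groups of k same-code epochs per block.

    Within each (block, stimulus-code) group, epochs are taken in
    presentation order and averaged k at a time; leftovers (< k) are
    discarded, so each group yields floor(reps / k) averaged trials.
    Labels are preserved (all members of a group share one).  k = 1 is the
    identity.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    out_epochs, out_labels, out_codes, out_blocks = [], [], [], []
    for b in np.unique(epochs.blocks):
        for c in np.unique(epochs.codes[epochs.blocks == b]):
            idx = np.flatnonzero((epochs.blocks == b) & (epochs.codes == c))
            if len(idx) < k:
                raise ValueError(
                    f"group (block={b}, code={c}) has {len(idx)} epochs, fewer than k={k}"
                )
            n_groups = len(idx) // k
            for g in range(n_groups):
                members = idx[g * k : (g + 1) * k]
                out_epochs.append(epochs.epochs[members].mean(axis=0))
                out_labels.append(epochs.labels[members[0]])
                out_codes.append(c)
                out_blocks.append(b)
    return EpochSet(
        epochs=np.stack(out_epochs),
        fs=epochs.fs,
        labels=np.array(out_labels),
        codes=np.array(out_codes),
        blocks=np.array(out_blocks),
        channel_names=list(epochs.channel_names),
        window_ms=epochs.window_ms,
    )


def _attended_code(block_set: EpochSet) -> int:
    codes = np.unique(block_set.codes[block_set.labels == TARGET])
    if len(codes) != 1:
        raise ValueError(f"block has {len(codes)} attended codes; expected exactly 1")
    return int(codes[0])


def _score_block_mdm(block_set: EpochSet, stc, mdm: MDM) -> tuple[int, int]:
    """(correct, total) command decisions for one held-out block."""
    attended = _attended_code(block_set)
    codes = np.unique(block_set.codes)
    k_cmds = len(codes)
    per_code = {int(c): np.flatnonzero(block_set.codes == c) for c in codes}
    n_rounds = min(len(v) for v in per_code.values())
    correct = 0
    for r in range(n_rounds):
        eps = np.stack([block_set.epochs[per_code[c][r]] for c in range(1, k_cmds + 1)])
        covs = stc.transform(eps)
        decision = command_select({c: covs[c - 1] for c in range(1, k_cmds + 1)}, mdm)
        correct += decision.decided_command == attended
    return correct, n_rounds


def _score_block_swlda(block_set: EpochSet, model: SWLDA) -> tuple[int, int]:
    attended = _attended_code(block_set)
    codes = np.unique(block_set.codes)
    k_cmds = len(codes)
    per_code = {int(c): np.flatnonzero(block_set.codes == c) for c in codes}
    n_rounds = min(len(v) for v in per_code.values())
    feats_all = decimate_epochs(block_set.epochs, block_set.fs)
    correct = 0
    for r in range(n_rounds):
        feats = {c: feats_all[per_code[c][r]] for c in range(1, k_cmds + 1)}
        decision = swlda_command_select(feats, model)
        correct += decision.decided_command == attended
    return correct, n_rounds


def evaluate(
    dataset: EpochSet,
    K: int,
    k_range=(1, 2, 3, 4, 5),
    n_folds: int = 5,
    seed: int | None = None,
    classifiers=("mdm", "swlda"),
) -> AccuracyTable:
    """Cross-validated command accuracy vs averaging depth for MDM and SWLDA.

    Folds split whole selection blocks (never trials) so prototypes and
    classifiers are always fit on blocks disjoint from those scored.  For
    each depth k, training and test epochs are k-averaged alike, keeping
    the covariance noise scale consistent between fitting and scoring.

    Parameters
    ----------
    dataset : epochs carrying block structure and 1..K stimulus codes.
    K : command count of the paradigm (chance level is 100/K percent).
    k_range : averaging depths to sweep.
    n_folds : cross-validation folds over blocks.
    seed : controls the fold shuffle only (the data are given).
    """
    blocks = np.unique(dataset.blocks)
    if len(blocks) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} blocks, got {len(blocks)}")
    k_range = list(k_range)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc = {name: np.zeros((n_folds, len(k_range))) for name in classifiers}

    for f, (tr_i, te_i) in enumerate(kf.split(blocks)):
        tr_blocks, te_blocks = blocks[tr_i], blocks[te_i]
        train = dataset.subset(np.isin(dataset.blocks, tr_blocks))
        test = dataset.subset(np.isin(dataset.blocks, te_blocks))
        if "swlda" in classifiers:
            # canonical calibration: single-trial features; a linear score of
            # a k-averaged epoch equals the k-averaged single-trial score
            swlda = SWLDA().fit(decimate_epochs(train.epochs, train.fs), train.labels)
        for ki, k in enumerate(k_range):
            train_k = average_erps(train, k)
            test_k = average_erps(test, k)
            if "mdm" in classifiers:
                # the covariance feature is nonlinear in the trial, so the MDM
                # class means are fit at the same averaging depth as the test
                stc = SuperTrialCovariance().fit(train_k.epochs, train_k.labels)
                covs = stc.transform(train_k.epochs)
                mdm = MDM().fit(covs, train_k.labels)
                correct = total = 0
                for b in te_blocks:
                    c, t = _score_block_mdm(test_k.subset(test_k.blocks == b), stc, mdm)
                    correct, total = correct + c, total + t
                fold_acc["mdm"][f, ki] = 100.0 * correct / total
            if "swlda" in classifiers:
                correct = total = 0
                for b in te_blocks:
                    c, t = _score_block_swlda(test_k.subset(test_k.blocks == b), swlda)
                    correct, total = correct + c, total + t
                fold_acc["swlda"][f, ki] = 100.0 * correct / total

    rows = []
    for name in classifiers:
        for ki, k in enumerate(k_range):
            accs = fold_acc[name][:, ki]
            rows.append(
                {
                    "classifier": name,
                    "k": k,
                    "mean_accuracy": round(float(accs.mean()), 1),
                    "sd_accuracy": round(float(accs.std(ddof=1)), 1),
                }
            )
    p_values = {}
    if "mdm" in classifiers and "swlda" in classifiers:
        for ki, k in enumerate(k_range):
            p_values[k] = ranksum_compare(fold_acc["mdm"][:, ki], fold_acc["swlda"][:, ki])
    return AccuracyTable(
        table=pd.DataFrame(rows),
        p_values=p_values,
        chance_percent=chance_level(K),
        fold_accuracies=fold_acc,
        metadata={
            "seed": seed,
            "n_folds": n_folds,
            "k_range": k_range,
            "aggregation": "mean +/- SD over cross-validation folds (blocks held out)",
        },
    )


def ranksum_compare(acc_a, acc_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration when both samples are small (n <= 8) and tie-free;
    normal approximation with tie correction otherwise.  Identical or
    degenerate single-element samples give p = 1.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and max(len(a), len(b)) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def chance_level(K: int) -> float:
    """Random-guessing command accuracy, 100/K percent to one decimal."""
    if K < 2:
        raise ValueError("K must be at least 2 to define a decision problem")
    return round(100.0 / K, 1)


def grand_average(epochs: EpochSet) -> GrandAverage:
    """Per-class mean waveform and per-sample standard error (SD/sqrt(n))."""
    out = {}
    for name, lab in (("target", TARGET), ("nontarget", NONTARGET)):
        members = epochs.epochs[epochs.labels == lab]
        if len(members) < 2:
            raise ValueError(f"class '{name}' has {len(members)} trials; need at least 2")
        out[name] = (
            members.mean(axis=0),
            members.std(axis=0, ddof=1) / np.sqrt(len(members)),
            len(members),
        )
    return GrandAverage(
        target_mean=out["target"][0],
        target_se=out["target"][1],
        nontarget_mean=out["nontarget"][0],
        nontarget_se=out["nontarget"][1],
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        n_target=out["target"][2],
        n_nontarget=out["nontarget"][2],
    )
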