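"""Gini-ordered decision tree over fingerprint RPKM features.

Each decision node asks one question — "does this sample's RPKM on individual
X's fingerprint reach X's calibrated threshold?" — and commits the above
branch as the leaf for X.  The order of questions is chosen greedily: at each
node the remaining fingerprint minimising the branch-weighted Gini impurity
Gini_index(D, a) = Σ_v |D^v|/|D| · Gini(D^v), with Gini(D) = 1 − Σ_k p_k²,
is asked first.  Thresholds are fixed upstream from ROC geometry and are not
re-learned here.  A sample exceeding no threshold falls through to the single
unlabeled leaf, the outcome for out-of-cohort donors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

UNLABELED = "unlabeled"

DECISION = "decision"
LEAF = "leaf"


@dataclass
class TreeNode:
    kind: str                          # "decision" | "leaf" | "unlabeled"
    individual_id: str | None = None   # decision: attribute; leaf: label
    threshold: float | None = None
    above: "TreeNode | None" = None
    below: "TreeNode | None" = None
    n_train_above: int = 0
    above_purity: float | None = None  # fraction of above-branch samples truly the label


def gini(labels: Sequence[str]) -> float:
    """Gini impurity 1 − Σ p_k² of a labeled multiset."""
    labels = list(labels)
    if not labels:
        raise ValueError("gini of an empty multiset is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1 - np.sum(p**2))


def gini_index(
    sample_labels: Mapping[str, str],
    attribute: tuple[str, float],
    rpkm_lookup: Mapping[str, Mapping[str, float]],
) -> float:
    """Branch-weighted Gini of splitting D by one fingerprint's threshold.

    ``attribute`` is (individual_id, threshold); ``rpkm_lookup`` maps
    sample_id -> {individual_id: rpkm}.  The two branches are RPKM >= threshold
    (above) and < threshold (below); an empty branch contributes 0.
    """
    ind, thr = attribute
    if not sample_labels:
        raise ValueError("empty sample set")
    above, below = [], []
    for sid, lab in sample_labels.items():
        if ind not in rpkm_lookup[sid]:
            raise ValueError(f"sample {sid!r} lacks an RPKM value for {ind!r}")
        (above if rpkm_lookup[sid][ind] >= thr else below).append(lab)
    n = len(sample_labels)
    total = 0.0
    for branch in (above, below):
        if branch:
            total += len(branch) / n * gini(branch)
    return total


def build_tree(
    training_rpkm: pd.DataFrame,
    thresholds: Mapping[str, float],
    sample_labels: Mapping[str, str],
) -> TreeNode:
    """Greedy Gini-ordered chain of fingerprint decisions.

    ``training_rpkm`` is individuals (fingerprints) × samples.  At each node
    the attribute minimising Gini_index on the node's sample set is selected;
    its above branch becomes that individual's leaf, the below branch recurses
    over the remaining attributes, ending in the unlabeled leaf.  Ties are
    broken by higher above-branch recall of the attribute's own individual,
    then by individual_id; nodes whose sample set is exhausted order the
    remaining attributes by individual_id.
    """
    inds = sorted(thresholds)
    if sorted(training_rpkm.index) != inds:
        raise ValueError("thresholds and RPKM rows must cover the same individuals")
    if len(set(inds)) != len(thresholds):
        raise ValueError("duplicate fingerprint per individual")
    lookup = {
        sid: {ind: float(training_rpkm.at[ind, sid]) for ind in inds}
        for sid in training_rpkm.columns
    }
    for sid in sample_labels:
        if sid not in lookup:
            raise ValueError(f"training sample {sid!r} lacks abundance values")

    def recurse(samples: dict[str, str], remaining: list[str]) -> TreeNode:
        if not remaining:
            return TreeNode(kind=LEAF, individual_id=UNLABELED)
        if samples:
            scored = []
            for ind in remaining:
                gi = gini_index(samples, (ind, thresholds[ind]), lookup)
                own = [s for s, lab in samples.items() if lab == ind]
                above_own = sum(
                    1 for s in own if lookup[s][ind] >= thresholds[ind]
                )
                recall = above_own / len(own) if own else 0.0
                scored.append((gi, -recall, ind))
            scored.sort()
            best = scored[0][2]
        else:
            best = remaining[0]  # individual_id order
        thr = thresholds[best]
        above = {s: lab for s, lab in samples.items() if lookup[s][best] >= thr}
        below = {s: lab for s, lab in samples.items() if lookup[s][best] < thr}
        purity = (
            sum(1 for lab in above.values() if lab == best) / len(above)
            if above
            else None
        )
        return TreeNode(
            kind=DECISION,
            individual_id=best,
            threshold=thr,
            above=TreeNode(kind=LEAF, individual_id=best),
            below=recurse(below, [i for i in remaining if i != best]),
            n_train_above=len(above),
            above_purity=purity,
        )

    return recurse(dict(sample_labels), inds)


def identify(tree: TreeNode, abundances: Mapping[str, float]) -> str:
    """Route one sample's fingerprint RPKMs through the tree to a label."""
    node = tree
    while node.kind == DECISION:
        if node.individual_id not in abundances:
            raise ValueError(f"missing abundance for fingerprint {node.individual_id!r}")
        value = abundances[node.individual_id]
        node = node.above if value >= node.threshold else node.below
        assert node is not None
    return node.individual_id or UNLABELED


@dataclass
class EvalReport:
    accuracy: float
    confusion: pd.DataFrame            # rows = predicted, columns = true
    precision: dict[str, float]
    recall: dict[str, float]
    predictions: dict[str, str] = field(default_factory=dict)


def evaluate_identifier(
    tree: TreeNode,
    test_rpkm: pd.DataFrame,
    true_labels: Mapping[str, str],
) -> EvalReport:
    """Confusion matrix, per-individual precision/recall and overall accuracy.

    Unlabeled assignments count as errors for in-cohort samples.  Matrix rows
    are predicted labels, columns true labels.
    """
    if not true_labels:
        raise ValueError("empty test set")
    preds = {}
    for sid in true_labels:
        abund = {ind: float(test_rpkm.at[ind, sid]) for ind in test_rpkm.index}
        preds[sid] = identify(tree, abund)
    trues = sorted(set(true_labels.values()))
    pred_labels = sorted(set(preds.values()) | set(trues) | {UNLABELED})
    confusion = pd.DataFrame(0, index=pred_labels, columns=trues)
    for sid, t in true_labels.items():
        confusion.at[preds[sid], t] += 1
    correct = sum(1 for sid, t in true_labels.items() if preds[sid] == t)
    precision = {}
    recall = {}
    for ind in trues:
        tp = int(confusion.at[ind, ind]) if ind in confusion.index else 0
        row = int(confusion.loc[ind].sum()) if ind in confusion.index else 0
        col = int(confusion[ind].sum())
        precision[ind] = tp / row if row else float("nan")
        recall[ind] = tp / col if col else float("nan")
    return EvalReport(
        accuracy=correct / len(true_labels),
        confusion=confusion,
        precision=precision,
        recall=recall,
        predictions=preds,
    )


def tree_to_json(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialise the tree as a node list with child indices."""
    nodes: list[dict] = []

    def visit(node: TreeNode) -> int:
        idx = len(nodes)
        nodes.append({})
        entry = {
            "kind": node.kind,
            "individual_id": node.individual_id,
            "threshold": node.threshold,
            "n_train_above": node.n_train_above,
            "above_purity": node.above_purity,
        }
        if node.kind == DECISION:
            entry["above"] = visit(node.above)
            entry["below"] = visit(node.below)
        nodes[idx] = entry
        return idx

    visit(tree)
    text = json.dumps({"nodes": nodes}, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def tree_from_json(source: str | Path) -> TreeNode:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    nodes = json.loads(text)["nodes"]

    def build(idx: int) -> TreeNode:
        e = nodes[idx]
        node = TreeNode(
            kind=e["kind"],
            individual_id=e["individual_id"],
            threshold=e["threshold"],
            n_train_above=e.get("n_train_above", 0),
            above_purity=e.get("above_purity"),
        )
        if e["kind"] == DECISION:
            node.above = build(e["above"])
            node.below = build(e["below"])
        return node

    return build(0)
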