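"""Brute-force reference implementations used by the metric tests."""


def concordance_oracle(scores, labels):
    """O(n^2) pairwise concordance with ties counted 1/2 (ROC-AUC)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def ap_rank_walk_oracle(scores, labels):
    """Walk ranks in decreasing-score order (tied scores grouped) and
    accumulate (delta recall) * precision (step-wise average precision)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    tp = fp = 0
    prev_recall = 0.0
    ap = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]]
            fp += 1 - labels[order[j]]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap
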