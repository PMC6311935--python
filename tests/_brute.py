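"""Independent brute-force re-implementation of the predictor and the
per-site contribution map, written with plain Python loops over explicit
index arithmetic. Used as the oracle against the vectorized package code;
shares nothing with it beyond the parameter arrays it is handed."""

import math

from mampep.alphabet import AA_INDEX


def brute_features(model, seq):
    """Per-level post-activation feature maps via explicit loops."""
    L = len(seq)
    x = [[float(model.embedding[AA_INDEX[c], d])
          for d in range(model.embedding.shape[1])] for c in seq]
    levels = []
    for lvl in range(len(model.conv_w)):
        W = model.conv_w[lvl]   # (F, C, K)
        b = model.conv_b[lvl]
        F, C, K = W.shape
        pl = (K - 1) // 2
        out = []
        for k in range(L):
            row = []
            for f in range(F):
                z = float(b[f])
                for t in range(K):
                    src = k + t - pl
                    if 0 <= src < L:
                        for c in range(C):
                            z += float(W[f, c, t]) * x[src][c]
                row.append(z if z >= 0 else model.arch.leaky_slope * z)
            out.append(row)
        levels.append(out)
        x = out
    return levels


def brute_site_scores(model, seq):
    """Triple sum over levels i, filters j and the site k feature."""
    levels = brute_features(model, seq)
    L = len(seq)
    scores = []
    for k in range(L):
        s = 0.0
        for i, feats in enumerate(levels):
            inner = 0.0
            for j in range(len(feats[k])):
                inner += float(model.gap_w[i][j]) * feats[k][j]
            s += float(model.fusion_w[i]) * inner
        scores.append(s)
    return scores


def brute_probability(model, seq):
    levels = brute_features(model, seq)
    L = len(seq)
    logit = 0.0
    for i, feats in enumerate(levels):
        c = 0.0
        for j in range(len(feats[0])):
            pooled = sum(feats[k][j] for k in range(L)) / L
            c += float(model.gap_w[i][j]) * pooled
        logit += float(model.fusion_w[i]) * c
    return 1.0 / (1.0 + math.exp(-logit))
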