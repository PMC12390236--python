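"""Independent brute-force reimplementation of the evaluation metrics.

Direct per-sample summation with explicit loops, kept deliberately free
of any code shared with pdsense.modeling so it can serve as an oracle.
"""

import math


def brute_force_metrics(y_true, y_pred, class_of):
    n = len(y_true)
    sse = sum((t - p) ** 2 for t, p in zip(y_true, y_pred))
    sae = sum(abs(t - p) for t, p in zip(y_true, y_pred))
    mse = sse / n
    mae = sae / n
    mean_t = sum(y_true) / n
    mean_p = sum(y_pred) / n
    sst = sum((t - mean_t) ** 2 for t in y_true)
    r2 = 1.0 - sse / sst
    cov = sum((t - mean_t) * (p - mean_p) for t, p in zip(y_true, y_pred))
    var_p = sum((p - mean_p) ** 2 for p in y_pred)
    r = cov / math.sqrt(sst * var_p)
    classes = sorted({class_of(t) for t in y_true})
    mae_k, mse_k = {}, {}
    for k in classes:
        members = [
            (t, p) for t, p in zip(y_true, y_pred) if class_of(t) == k
        ]
        mae_k[k] = sum(abs(t - p) for t, p in members) / len(members)
        mse_k[k] = sum((t - p) ** 2 for t, p in members) / len(members)
    c = len(classes)
    bmae = sum(mae_k.values()) / c
    bmse = sum(mse_k.values()) / c
    return {
        "mse": mse, "r2": r2, "mae": mae, "r": r,
        "per_class_mae": mae_k, "bmae": bmae, "bmse": bmse, "n_classes": c,
    }
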