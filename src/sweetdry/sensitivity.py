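"""Connection-weight (Yoon) global sensitivity of outputs to inputs.

For input i and output j the relative importance is the signed share of the
summed weight products routed through the hidden layer,

    RI_ij (%) = sum_k W1[k,i] W2[j,k] / sum_i sum_k W1[k,i] W2[j,k] * 100,

so the importances of all inputs sum to 100% for every output by
construction (the denominator is signed, and individual entries may be
negative or exceed 100). Biases do not enter. An unsigned (absolute-value)
variant is available for outputs whose signed denominator nearly cancels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import INPUT_LABELS, RESPONSES

__all__ = ["yoon_relative_importance", "rank_influences"]


def yoon_relative_importance(results, signed: bool = True) -> pd.DataFrame:
    """Relative importance matrix (inputs x outputs), in percent.

    Parameters
    ----------
    results : MLPResults
        A trained network (only W1 and W2 are used).
    signed : bool
        If True (default) use the signed sums as printed in the study's
        sensitivity figures; if False take absolute values of the weight
        products (Garson-style), which is robust when the signed
        denominator is near zero.
    """
    W1, W2 = results.W1, results.W2          # (h x i), (o x h)
    S = W2 @ W1                              # o x i, sum_k W2[j,k] W1[k,i]
    if not signed:
        S = np.abs(W2) @ np.abs(W1)
    denom = S.sum(axis=1)                    # per output j
    bad = np.abs(denom) < 1e-12
    if np.any(bad):
        names = [_output_names(results)[j] for j in np.flatnonzero(bad)]
        raise ValueError("sign-degenerate denominator (|sum| < 1e-12) for "
                         f"output(s) {names}; consider signed=False")
    RI = 100.0 * S / denom[:, None]          # o x i
    return pd.DataFrame(RI.T, index=_input_names(results),
                        columns=_output_names(results))


def rank_influences(ri: pd.DataFrame, output: str) -> list[tuple[str, float]]:
    """Inputs sorted by descending importance for one output.

    Ties keep the original input order (stable sort).
    """
    if output not in ri.columns:
        raise KeyError(f"unknown output {output!r}")
    col = ri[output]
    order = np.argsort(-col.to_numpy(), kind="stable")
    return [(col.index[k], float(col.iloc[k])) for k in order]


def _input_names(results) -> list[str]:
    n_in = results.W1.shape[1]
    if n_in == len(INPUT_LABELS):
        return list(INPUT_LABELS)
    return [f"input_{i+1}" for i in range(n_in)]


def _output_names(results) -> list[str]:
    n_out = results.W2.shape[0]
    if n_out == len(RESPONSES):
        return list(RESPONSES)
    return [f"output_{j+1}" for j in range(n_out)]
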