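"""Optimal architecture configurations shipped as presets.

One configuration per look-back window, as selected by minimising the
cross-validation binary cross-entropy on the original corpus.  The
24-month and 12-month windows share a configuration; the 6-month window
favours a wider embedding but a much smaller dense cascade.
"""

from __future__ import annotations

__all__ = ["PRESETS"]

PRESETS: dict[str, dict] = {
    "infinite": dict(
        embedding_dim=64, lstm_dim=128, lstm_dropout=0.3,
        n_dense=5, dense_max_dim=128, dense_dropout=0.0,
    ),
    "24m": dict(
        embedding_dim=64, lstm_dim=128, lstm_dropout=0.15,
        n_dense=4, dense_max_dim=64, dense_dropout=0.0,
    ),
    "12m": dict(
        embedding_dim=64, lstm_dim=128, lstm_dropout=0.15,
        n_dense=4, dense_max_dim=64, dense_dropout=0.0,
    ),
    "6m": dict(
        embedding_dim=256, lstm_dim=128, lstm_dropout=0.3,
        n_dense=2, dense_max_dim=16, dense_dropout=0.0,
    ),
}
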