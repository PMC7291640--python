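"""Random hyperparameter search over per-parameter candidate lists."""

from __future__ import annotations

import numpy as np

from .specs import ArchitectureSpec, SearchSpace

__all__ = ["random_search", "sample_architecture"]


def random_search(space: SearchSpace, evaluate, minimize: bool = True):
    """Draw ``n_trials`` configurations uniformly from the candidate lists
    and keep the best-scoring one.

    ``evaluate(config_dict)`` returns a score; lower wins by default.
    Ties keep the earlier draw; the draw sequence is fully determined by
    ``space.seed``.  Returns ``(best_config, best_score, trials)``.
    """
    rng = np.random.default_rng(space.seed)
    keys = sorted(space.values)
    best_cfg, best_score = None, None
    trials = []
    for _ in range(space.n_trials):
        cfg = {k: space.values[k][rng.integers(len(space.values[k]))] for k in keys}
        score = evaluate(cfg)
        trials.append((cfg, score))
        better = (
            best_score is None
            or (score < best_score if minimize else score > best_score)
        )
        if better:
            best_cfg, best_score = cfg, score
    return best_cfg, best_score, trials


def sample_architecture(hidden_type: str, cfg: dict) -> ArchitectureSpec:
    """Build an ArchitectureSpec from a search-space draw, filling in the
    fields the draw does not set."""
    fields = {k: v for k, v in cfg.items() if k in ArchitectureSpec.__dataclass_fields__}
    if hidden_type != "dconv":
        fields.pop("n_dconv_layers", None)
    elif "n_dconv_layers" not in fields:
        fields["n_dconv_layers"] = 2
    return ArchitectureSpec(hidden_type=hidden_type, **fields)
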