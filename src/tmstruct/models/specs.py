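"""Hyperparameter records, target groups and receptive-field analytics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "TargetDef", "TARGETS", "TARGET_GROUPS", "group_targets",
    "ArchitectureSpec", "TrainConfig", "TreeParams", "SearchSpace",
    "receptive_field", "dilated_window_positions",
]


@dataclass(frozen=True)
class TargetDef:
    """One prediction target: its output kind and dimensionality."""

    name: str
    kind: str   # linear | binary | categorical
    dim: int


TARGETS = {
    t.name: t for t in (
        TargetDef("z", "linear", 1),
        TargetDef("topo", "categorical", 4),
        TargetDef("flex_cont", "linear", 1),
        TargetDef("flex_bin", "binary", 1),
        TargetDef("phi", "linear", 1),
        TargetDef("psi", "linear", 1),
        TargetDef("ss3", "categorical", 3),
        TargetDef("rsa_mono", "linear", 1),
        TargetDef("rsa_cplx", "linear", 1),
        TargetDef("rsa_change", "linear", 1),
    )
}

#: Related targets share one network: depth with topology, the two
#: flexibility variants, the two torsions, the three accessibilities;
#: secondary structure is predicted best on its own.
TARGET_GROUPS = {
    "z_topology": ("z", "topo"),
    "flexibility": ("flex_cont", "flex_bin"),
    "torsion": ("phi", "psi"),
    "rsa": ("rsa_mono", "rsa_cplx", "rsa_change"),
    "secondary_structure": ("ss3",),
}


def group_targets() -> list:
    """The five target groups as lists of :class:`TargetDef`."""
    return [[TARGETS[n] for n in names] for names in TARGET_GROUPS.values()]


@dataclass
class ArchitectureSpec:
    """Everything needed to build one network.

    ``hidden_type`` selects the hidden stack: plain convolutions ('conv'),
    blocks of dilated convolutions with dilation d_l = 2^(l-1) per block
    position ('dconv'), or bidirectional LSTM layers ('lstm').  ``w`` is
    the (odd) convolution window; ``residual`` adds identity mappings
    ('add' aligns dimensions with a window-1 convolution on the first
    hidden layer, 'concat' appends the layer input to its output).
    """

    hidden_type: str
    n_hidden_layers: int = 2
    n_hidden_neurons: int = 16
    w: int = 3
    n_dconv_layers: int | None = None
    residual: str = "none"
    n_embedding: int = 8
    n_dense_layers: int = 1
    n_dense_neurons: int = 16

    def __post_init__(self):
        if self.hidden_type not in ("conv", "dconv", "lstm"):
            raise ValueError(f"unknown hidden_type {self.hidden_type!r}")
        if self.w % 2 == 0 or self.w < 1:
            raise ValueError("window size w must be odd and positive")
        if self.n_embedding < 1:
            raise ValueError("n_embedding must be >= 1")
        if self.residual not in ("none", "add", "concat"):
            raise ValueError(f"unknown residual mode {self.residual!r}")
        if self.hidden_type == "dconv":
            if self.n_dconv_layers is None or self.n_dconv_layers < 2:
                raise ValueError("dconv requires n_dconv_layers >= 2")
        elif self.n_dconv_layers is not None:
            raise ValueError(
                f"n_dconv_layers is only valid with hidden_type='dconv', "
                f"not {self.hidden_type!r}"
            )


@dataclass
class TrainConfig:
    """Optimisation schedule: Adam with early stopping and lr decay.

    One "iteration" is a full pass through the training samples (an
    epoch).  After ``patience_lr`` epochs without validation improvement
    the learning rate is multiplied by ``lr_factor``; after
    ``patience_stop`` the training stops and the best-epoch weights are
    restored.
    """

    batch_size: int = 4
    initial_lr: float = 1e-2
    patience_stop: int = 10
    patience_lr: int = 5
    lr_factor: float = 0.1
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.patience_lr < self.patience_stop:
            raise ValueError("patience_lr must be smaller than patience_stop")


@dataclass
class TreeParams:
    """Hyperparameters of the windowed tree models."""

    n_trees: int = 100
    n_features: float = 0.5       # fraction of features per tree
    n_min_samples: int = 1        # minimum samples per leaf (RF)
    w: int = 5                    # window size
    # boosting only:
    n_samples: float = 1.0        # subsample fraction
    r: float = 0.1                # learning rate
    n_depth: int = 4              # maximum depth
    gamma: float = 0.0
    n_min_child_weight: float = 1.0

    def __post_init__(self):
        if not 0 < self.n_features <= 1 or not 0 < self.n_samples <= 1:
            raise ValueError("fractions must be in (0, 1]")
        if self.w % 2 == 0 or self.w < 1:
            raise ValueError("window size w must be odd and positive")


@dataclass
class SearchSpace:
    """Per-hyperparameter candidate lists for random search."""

    values: dict = field(default_factory=dict)
    n_trials: int = 4
    seed: int = 0

    def __post_init__(self):
        for key, vals in self.values.items():
            if not vals:
                raise ValueError(f"empty candidate list for {key!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def receptive_field(spec: ArchitectureSpec):
    """Number of sequence positions that can influence one output.

    conv: 1 + n_layers * (w - 1); dconv: each block of n_dconv_layers
    layers contributes (w - 1) * sum(2^(l-1)); lstm: the full sequence
    (returned as ``math.inf``).
    """
    if spec.hidden_type == "lstm":
        return math.inf
    if spec.hidden_type == "conv":
        return 1 + spec.n_hidden_layers * (spec.w - 1)
    per_block = sum(2 ** (l - 1) for l in range(1, spec.n_dconv_layers + 1))
    return 1 + spec.n_hidden_layers * (spec.w - 1) * per_block


def dilated_window_positions(i: int, w: int, d: int) -> list:
    """Input positions covered by a dilated window centred at ``i``."""
    if w % 2 == 0 or w < 1:
        raise ValueError("w must be odd and positive")
    if d < 1:
        raise ValueError("dilation must be >= 1")
    half = (w - 1) // 2
    return [i + k * d for k in range(-half, half + 1)]
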