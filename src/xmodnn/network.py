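"""Modular network construction and forward pass.

Every hierarchy node at levels C, B and A — plus the single output node O —
becomes a small neural module; level-D genes are raw inputs, not modules.
A module's first internal layer reads the concatenation of its children's
outputs (one scalar per gene child, the last-internal-layer width per module
child).  Each module also carries an auxiliary classifier head reading its
own last internal layer; heads feed nothing forward and exist only for the
weighted multi-loss and for evaluation.

Internal layers use tanh except the last, which is the identity; heads are
linear (softmax happens inside the loss).  Biases are disabled on the first
internal layer, the last (identity) internal layer and the head; the middle
layers keep theirs.  Weights are initialised with normalised-Xavier scaling:
uniform on +-sqrt(6 / (fan_in + fan_out)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .hierarchy import FunctionalHierarchy


@dataclass
class ModuleSpec:
    layer_widths: list[int] = field(default_factory=lambda: [3, 3, 3])
    activation: str = "tanh"
    input_bias: bool = False
    head_bias: bool = False
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not self.layer_widths or any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer_widths must be non-empty and positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.activation != "tanh":
            raise ValueError("only tanh internal activation is supported")

    def layer_has_bias(self, layer: int) -> bool:
        n = len(self.layer_widths)
        if layer == 0:
            return self.input_bias
        if layer == n - 1:  # identity layer, bias disabled like the head
            return False
        return True


@dataclass
class ModuleParams:
    """Per-layer weight matrices W[l] (in x out), optional biases, and head."""

    W: list[np.ndarray]
    b: list[np.ndarray | None]
    W_head: np.ndarray
    b_head: np.ndarray | None

    def arrays(self) -> Iterator[tuple[str, np.ndarray]]:
        for l, w in enumerate(self.W):
            yield f"W{l}", w
            if self.b[l] is not None:
                yield f"b{l}", self.b[l]
        yield "W_head", self.W_head
        if self.b_head is not None:
            yield "b_head", self.b_head

    def copy(self) -> "ModuleParams":
        return ModuleParams(
            [w.copy() for w in self.W],
            [None if x is None else x.copy() for x in self.b],
            self.W_head.copy(),
            None if self.b_head is None else self.b_head.copy(),
        )

    def n_params(self) -> int:
        return sum(a.size for _, a in self.arrays())


@dataclass
class ModularNetwork:
    hierarchy: FunctionalHierarchy
    spec: ModuleSpec
    seed: int
    modules: dict[str, ModuleParams]
    # module id -> ordered (child_id, kind) with kind in {"gene", "module"}
    inbound: dict[str, list[tuple[str, str]]]

    @property
    def gene_order(self) -> list[str]:
        return self.hierarchy.gene_order

    @property
    def module_order(self) -> list[str]:
        return self.hierarchy.module_order

    def input_width(self, module_id: str) -> int:
        last = self.spec.layer_widths[-1]
        return sum(1 if kind == "gene" else last
                   for _, kind in self.inbound[module_id])

    def n_params(self) -> int:
        return sum(m.n_params() for m in self.modules.values())

    def copy_params(self) -> dict[str, ModuleParams]:
        return {mid: m.copy() for mid, m in self.modules.items()}

    def set_params(self, params: dict[str, ModuleParams]) -> None:
        self.modules = {mid: m.copy() for mid, m in params.items()}


@dataclass
class ForwardResult:
    """Activations retained per module for the loss and for LRP.

    ``inputs[m]``: (n, in) concatenated child outputs;
    ``pre[m][l]`` / ``post[m][l]``: pre-/post-activation of internal layer l;
    ``head_outputs[m]``: (n, n_classes) linear head scores.
    """

    inputs: dict[str, np.ndarray]
    pre: dict[str, list[np.ndarray]]
    post: dict[str, list[np.ndarray]]
    head_outputs: dict[str, np.ndarray]

    def module_output(self, module_id: str) -> np.ndarray:
        return self.post[module_id][-1]


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_network(h: FunctionalHierarchy, spec: ModuleSpec, seed: int) -> ModularNetwork:
    """Initialise a modular network; identical seeds give identical parameters."""
    if not h.ids_at("C"):
        raise ValueError("hierarchy has no level-C modules")
    rng = np.random.default_rng(seed)
    last = spec.layer_widths[-1]

    inbound: dict[str, list[tuple[str, str]]] = {}
    modules: dict[str, ModuleParams] = {}
    for mid in h.module_order:  # deterministic order drives RNG stream
        kids = h.children_sorted(mid)
        inbound[mid] = [
            (c, "gene" if h.level_of(c) == "D" else "module") for c in kids
        ]
        in_w = sum(1 if k == "gene" else last for _, k in inbound[mid])
        W, b = [], []
        for l, out_w in enumerate(spec.layer_widths):
            W.append(xavier_uniform(rng, in_w, out_w))
            b.append(np.zeros(out_w) if spec.layer_has_bias(l) else None)
            in_w = out_w
        W_head = xavier_uniform(rng, last, spec.n_classes)
        b_head = np.zeros(spec.n_classes) if spec.head_bias else None
        modules[mid] = ModuleParams(W, b, W_head, b_head)
    return ModularNetwork(h, spec, seed, modules, inbound)


def forward(net: ModularNetwork, x: np.ndarray) -> ForwardResult:
    """Run the network on a (n_samples, n_genes) batch (or a single vector).

    Modules are evaluated children-first; the O-module head carries the
    global class score.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("non-finite value in input")
    if x.shape[1] != len(net.gene_order):
        raise ValueError(
            f"input has {x.shape[1]} features, expected {len(net.gene_order)} genes"
        )
    gene_col = {g: i for i, g in enumerate(net.gene_order)}
    n_internal = len(net.spec.layer_widths)

    inputs: dict[str, np.ndarray] = {}
    pre: dict[str, list[np.ndarray]] = {}
    post: dict[str, list[np.ndarray]] = {}
    heads: dict[str, np.ndarray] = {}
    for mid in net.module_order:
        cols = [
            x[:, [gene_col[c]]] if kind == "gene" else post[c][-1]
            for c, kind in net.inbound[mid]
        ]
        a = np.concatenate(cols, axis=1)
        inputs[mid] = a
        p = net.modules[mid]
        zs, hs = [], []
        for l in range(n_internal):
            z = a @ p.W[l]
            if p.b[l] is not None:
                z = z + p.b[l]
            a = np.tanh(z) if l < n_internal - 1 else z
            zs.append(z)
            hs.append(a)
        pre[mid], post[mid] = zs, hs
        head = hs[-1] @ p.W_head
        if p.b_head is not None:
            head = head + p.b_head
        heads[mid] = head
    return ForwardResult(inputs, pre, post, heads)


def predict_proba(net: ModularNetwork, x: np.ndarray) -> np.ndarray:
    """Softmax class probabilities from the O-module head."""
    scores = forward(net, x).head_outputs[net.hierarchy.output_id]
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def predict(net: ModularNetwork, x: np.ndarray) -> np.ndarray:
    return predict_proba(net, x).argmax(axis=1)
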