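"""Generator and critic networks and the adversarial loss terms.

The generator is a fully connected encoder–decoder style network mapping a
source-omics profile (p features) to a target-omics profile (q features):
two hidden layers of 512 and 768 units, rectified activations throughout
including the output layer, which guarantees non-negative generated
expression.  The critic scores a target-omics profile with a single
unbounded output (two hidden layers, 256 and 128 units, rectified; identity
output so the Wasserstein score can be negative) and is kept approximately
Lipschitz by clipping every weight into ``[-clip_value, clip_value]`` after
each optimizer step, as in the original Wasserstein-GAN recipe.

Networks, backpropagation and the RMSprop optimizer are implemented directly
on numpy arrays; the layer sizes involved are small enough that dense BLAS
calls are all that is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .nmf import nmf_loss_and_grad

__all__ = [
    "GeneratorSpec",
    "CriticSpec",
    "MLP",
    "build_generator",
    "build_critic",
    "generate",
    "critic_loss",
    "generator_loss",
    "clip_weights",
    "RMSProp",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorSpec:
    input_dim: int
    output_dim: int
    hidden_dims: tuple[int, ...] = (512, 768)
    # rectified output enforces non-negative generated expression
    output_activation: str = "relu"

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1 or any(h < 1 for h in self.hidden_dims):
            raise ValueError("all layer dimensions must be positive")


@dataclass(frozen=True)
class CriticSpec:
    input_dim: int
    hidden_dims: tuple[int, ...] = (256, 128)
    clip_value: float = 0.01
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if self.input_dim < 1 or any(h < 1 for h in self.hidden_dims):
            raise ValueError("all layer dimensions must be positive")
        if self.clip_value <= 0:
            raise ValueError("clip_value must be > 0")


def _act(kind: str, z: np.ndarray) -> np.ndarray:
    if kind in ("relu", "relu_st"):
        return np.maximum(z, 0.0)
    if kind == "identity":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(kind: str, z: np.ndarray) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "relu_st":
        # straight-through rectifier: exact ReLU forward, identity backward.
        # An output feature clamped at zero for every sample would otherwise
        # receive an exactly-zero gradient and could never recover, which in
        # practice freezes a sizeable subset of target features at zero.
        return np.ones_like(z)
    if kind == "identity":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {kind!r}")


class MLP:
    """Dense feed-forward network with per-layer activations and backprop."""

    def __init__(self, dims: Iterable[int], activations: list[str], seed: int = 0):
        dims = list(dims)
        if len(activations) != len(dims) - 1:
            raise ValueError("need one activation per layer")
        self.activations = list(activations)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / fan_in)  # Kaiming-style uniform fan-in scaling
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def dims(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def forward(self, X: np.ndarray, want_cache: bool = False):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects "
                f"{self.weights[0].shape[0]}"
            )
        a = X
        pre: list[np.ndarray] = []
        post: list[np.ndarray] = [a]
        for W, b, act in zip(self.weights, self.biases, self.activations):
            z = a @ W + b
            a = _act(act, z)
            pre.append(z)
            post.append(a)
        if want_cache:
            return a, (pre, post)
        return a

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def backward(self, cache, d_out: np.ndarray):
        """Gradients of a scalar loss given dL/d(output).

        Returns ``(grads, d_input)`` where ``grads`` is a list of
        ``(dW, db)`` pairs, one per layer.
        """
        pre, post = cache
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)
        delta = d_out
        for i in range(len(self.weights) - 1, -1, -1):
            delta = delta * _act_grad(self.activations[i], pre[i])
            grads[i] = (post[i].T @ delta, delta.sum(axis=0))
            delta = delta @ self.weights[i].T
        return grads, delta

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in zip(self.weights, self.biases):
            out.extend([W, b])
        return out


def build_generator(spec: GeneratorSpec, seed: int = 0) -> MLP:
    dims = [spec.input_dim, *spec.hidden_dims, spec.output_dim]
    # the output rectifier is trained with a straight-through gradient so
    # that target features clamped at zero can still receive updates
    out_act = "relu_st" if spec.output_activation == "relu" else spec.output_activation
    acts = ["relu"] * len(spec.hidden_dims) + [out_act]
    net = MLP(dims, acts, seed=seed)
    net.spec = spec
    return net


def build_critic(spec: CriticSpec, seed: int = 0) -> MLP:
    dims = [spec.input_dim, *spec.hidden_dims, 1]
    acts = ["relu"] * len(spec.hidden_dims) + [spec.output_activation]
    net = MLP(dims, acts, seed=seed)
    net.spec = spec
    return net


def generate(G: MLP, X: np.ndarray) -> np.ndarray:
    """Deterministic generator forward pass; output is elementwise >= 0."""
    return G.forward(X)


def critic_loss(C: MLP, Y_real: np.ndarray, Y_fake: np.ndarray) -> float:
    """Critic objective: mean score of fakes minus mean score of reals.

    Minimizing drives real scores above fake scores.  Antisymmetric under
    swapping the two batches.
    """
    Y_real = np.atleast_2d(np.asarray(Y_real, float))
    Y_fake = np.atleast_2d(np.asarray(Y_fake, float))
    if Y_real.shape[0] == 0 or Y_fake.shape[0] == 0:
        raise ValueError("critic batches must be non-empty")
    if Y_real.shape[1] != Y_fake.shape[1]:
        raise ValueError("real and fake batches must have the same feature count")
    return float(C.forward(Y_fake).mean() - C.forward(Y_real).mean())


def generator_loss(
    C: MLP,
    G: MLP,
    X_batch: np.ndarray,
    Y_obs_batch: np.ndarray,
    obs_index: np.ndarray,
    U_ref: np.ndarray | None,
    alpha: float,
    beta: float,
    c: int,
    seed: int = 0,
    adversarial: bool = True,
    nmf_max_iter: int = 300,
) -> tuple[float, dict[str, float]]:
    """Composite generator objective (minimization convention).

    ``L = -mean C(G(X)) + alpha * centroid_loss(U_ref, G(X))
          + beta * MSE(Y_obs, G(X)[obs_index])``

    The adversarial and centroid terms use every row of the batch (observed
    and missing alike); the MSE term uses only rows with an observed target.
    Returns the total and a per-term breakdown for logging.
    """
    total, breakdown, _, _ = _generator_loss_full(
        C, G, X_batch, Y_obs_batch, obs_index, U_ref, alpha, beta, c,
        seed=seed, adversarial=adversarial, nmf_max_iter=nmf_max_iter,
        want_grads=False,
    )
    return total, breakdown


def _generator_loss_full(
    C: MLP,
    G: MLP,
    X_batch: np.ndarray,
    Y_obs_batch: np.ndarray,
    obs_index: np.ndarray,
    U_ref: np.ndarray | None,
    alpha: float,
    beta: float,
    c: int,
    seed: int = 0,
    adversarial: bool = True,
    nmf_max_iter: int = 300,
    want_grads: bool = True,
):
    """Shared forward(+backward) for the generator objective.

    Returns ``(total, breakdown, grads_or_None, Y_hat)`` where ``grads`` are
    per-parameter generator gradients.
    """
    import warnings as _warnings

    X_batch = np.atleast_2d(np.asarray(X_batch, float))
    b = X_batch.shape[0]
    Y_hat, g_cache = G.forward(X_batch, want_cache=True)
    q = Y_hat.shape[1]
    obs_index = np.asarray(obs_index, dtype=int)

    d_Yhat = np.zeros_like(Y_hat)
    breakdown: dict[str, float] = {"adversarial": 0.0, "nmf": 0.0, "mse": 0.0}

    if adversarial:
        scores, c_cache = C.forward(Y_hat, want_cache=True)
        breakdown["adversarial"] = float(-scores.mean())
        if want_grads:
            _, d_in = C.backward(c_cache, np.full_like(scores, -1.0 / b))
            d_Yhat += d_in

    if alpha > 0:
        if b < c:
            raise ValueError(
                f"batch of {b} rows cannot support the centroid loss with "
                f"c={c}; increase the batch size"
            )
        if U_ref is None:
            raise ValueError("centroid loss requested but no reference centroids given")
        nmf_val, nmf_grad = nmf_loss_and_grad(
            U_ref, Y_hat, c, seed=seed, max_iter=nmf_max_iter
        )
        breakdown["nmf"] = nmf_val
        if want_grads:
            d_Yhat += alpha * nmf_grad

    if beta > 0:
        if obs_index.size == 0:
            _warnings.warn(
                "no observed rows in batch; MSE term is 0", RuntimeWarning, stacklevel=2
            )
        else:
            Y_obs_batch = np.atleast_2d(np.asarray(Y_obs_batch, float))
            resid = Y_hat[obs_index] - Y_obs_batch
            n_el = resid.size
            breakdown["mse"] = float(np.mean(resid * resid))
            if want_grads:
                d_Yhat[obs_index] += beta * 2.0 * resid / n_el

    total = (
        breakdown["adversarial"] + alpha * breakdown["nmf"] + beta * breakdown["mse"]
    )
    grads = None
    if want_grads:
        grads, _ = G.backward(g_cache, d_Yhat)
    return total, breakdown, grads, Y_hat


def clip_weights(C: MLP) -> None:
    """Clamp every critic weight and bias into the clip box; idempotent."""
    cv = C.spec.clip_value
    for W, b in zip(C.weights, C.biases):
        np.clip(W, -cv, cv, out=W)
        np.clip(b, -cv, cv, out=b)


class RMSProp:
    """RMSprop with the original Wasserstein-GAN learning rate as default."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-5, rho: float = 0.9,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def save_checkpoint(path: str | Path, G: MLP, C: MLP, meta: dict) -> None:
    """Serialize both networks plus configuration metadata to one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for tag, net in (("G", G), ("C", C)):
        for i, (W, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"{tag}_W{i}"] = W
            arrays[f"{tag}_b{i}"] = b
    header = {
        "generator": {"dims": G.dims, "activations": G.activations,
                      "spec": _spec_dict(G.spec)},
        "critic": {"dims": C.dims, "activations": C.activations,
                   "spec": _spec_dict(C.spec)},
        "meta": meta,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _spec_dict(spec) -> dict:
    from dataclasses import asdict

    d = asdict(spec)
    d["hidden_dims"] = list(d["hidden_dims"])
    return d


def load_checkpoint(path: str | Path) -> tuple[MLP, MLP, dict]:
    data = np.load(path)
    header = json.loads(bytes(data["header"]).decode())
    gs = header["generator"]["spec"]
    cs = header["critic"]["spec"]
    G = build_generator(GeneratorSpec(gs["input_dim"], gs["output_dim"],
                                      tuple(gs["hidden_dims"]), gs["output_activation"]))
    C = build_critic(CriticSpec(cs["input_dim"], tuple(cs["hidden_dims"]),
                                cs["clip_value"], cs["output_activation"]))
    for tag, net in (("G", G), ("C", C)):
        for i in range(len(net.weights)):
            net.weights[i] = data[f"{tag}_W{i}"].copy()
            net.biases[i] = data[f"{tag}_b{i}"].copy()
    return G, C, header["meta"]
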