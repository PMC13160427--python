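"""The disentangling autoencoder.

One classifier encoder per categorical factor maps expression to logits over
that factor's categories; a residual encoder captures leftover variation.
Each factor owns a learned (K x code_dim) embedding table; its latent code is
the embedding row of the true label when the label is known, otherwise the
softmax-probability-weighted mixture of rows. Gaussian noise (standard
normal, no scale knob) is added to the residual during training only. The
decoder consumes the concatenation of all factor codes and the residual and
reconstructs either a log-normalized profile (mse mode) or negative-binomial
mean and per-gene dispersion (nb mode, both softplus-positive).

Factor code blocks are laid out contiguously in the order of the spec, so
e.g. a 2-dim batch block occupies the first two latent columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .data import FactorSpec

__all__ = ["ModelConfig", "LatentCode", "SCDRLModel", "compose_factor_code",
           "inject_noise", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and objective weights."""

    spec: FactorSpec
    encoder_hidden: tuple[int, ...] = (128, 64)
    decoder_hidden: tuple[int, ...] = (64, 128)
    reconstruction: str = "mse"  # 'mse' for lognorm input, 'nb' for raw counts
    lambda1: float = 0.5
    lambda2: float = 0.01
    lambda3: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.reconstruction not in ("mse", "nb"):
            raise ValueError("reconstruction must be 'mse' or 'nb'")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambdas must be non-negative")

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "encoder_hidden": list(self.encoder_hidden),
            "decoder_hidden": list(self.decoder_hidden),
            "reconstruction": self.reconstruction,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3": self.lambda3,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(
            spec=FactorSpec.from_dict(d["spec"]),
            encoder_hidden=tuple(d["encoder_hidden"]),
            decoder_hidden=tuple(d["decoder_hidden"]),
            reconstruction=d["reconstruction"],
            lambda1=d["lambda1"],
            lambda2=d["lambda2"],
            lambda3=d["lambda3"],
            seed=d["seed"],
        )


@dataclass
class LatentCode:
    """Per-factor logits/probabilities/codes plus the residual vector(s)."""

    logits: list[np.ndarray]
    probs: list[np.ndarray]
    codes: list[np.ndarray]
    residual: np.ndarray
    residual_noised: np.ndarray | None = None


def compose_factor_code(probs: np.ndarray, label: int | None,
                        embedding: np.ndarray) -> np.ndarray:
    """Latent code of one factor for one cell.

    With a known label the code is the embedding row of that category
    (one-hot weighting); otherwise it is the probability-weighted sum of
    embedding rows.
    """
    probs = np.asarray(probs, dtype=np.float64)
    embedding = np.asarray(embedding, dtype=np.float64)
    K = embedding.shape[0]
    if label is None or label < 0:
        return probs @ embedding
    if label >= K:
        raise ValueError(f"label {label} out of range for K={K}")
    return embedding[label].copy()


def inject_noise(residual: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Add standard-normal noise to the residual during training; identity in eval."""
    residual = np.asarray(residual, dtype=np.float64)
    if not training:
        return residual
    if rng is None:
        rng = np.random.default_rng()
    return residual + rng.standard_normal(residual.shape)


def _init_mlp(rng: np.random.Generator, sizes: list[int], prefix: str,
              params: dict) -> list[tuple[str, str]]:
    layers = []
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params[f"{prefix}_W{i}"] = Tensor(w, requires_grad=True)
        params[f"{prefix}_b{i}"] = Tensor(np.zeros(fan_out), requires_grad=True)
        layers.append((f"{prefix}_W{i}", f"{prefix}_b{i}"))
    return layers


class SCDRLModel:
    """Factor-specific encoders, residual encoder, embeddings and decoder."""

    def __init__(self, n_genes: int, config: ModelConfig):
        self.n_genes = int(n_genes)
        self.config = config
        self.spec = config.spec
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        self._encoders = []
        for f in self.spec.factors:
            sizes = [n_genes, *config.encoder_hidden, f.n_categories]
            self._encoders.append(_init_mlp(rng, sizes, f"enc_{f.name}", self.params))
        self._res_encoder = _init_mlp(
            rng, [n_genes, *config.encoder_hidden, self.spec.residual_dim],
            "enc_residual", self.params)
        for f in self.spec.factors:
            emb = rng.normal(0.0, 1.0, size=(f.n_categories, f.code_dim))
            self.params[f"emb_{f.name}"] = Tensor(emb, requires_grad=True)
        dec_sizes = [self.spec.latent_dim, *config.decoder_hidden]
        self._decoder = _init_mlp(rng, dec_sizes, "dec", self.params)
        if config.reconstruction == "mse":
            self._heads = {"out": _init_mlp(
                rng, [dec_sizes[-1], n_genes], "dec_out", self.params)}
        else:
            self._heads = {
                "mu": _init_mlp(rng, [dec_sizes[-1], n_genes], "dec_mu", self.params),
                "theta": _init_mlp(rng, [dec_sizes[-1], n_genes], "dec_theta",
                                   self.params),
            }

    # -- forward pieces ---------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def _mlp(self, layers, x: Tensor, final_linear: bool = True) -> Tensor:
        for i, (wname, bname) in enumerate(layers):
            x = x @ self.params[wname] + self.params[bname]
            if i < len(layers) - 1 or not final_linear:
                x = x.relu()
        return x

    def encoder_logits(self, x: Tensor) -> list[Tensor]:
        return [self._mlp(layers, x) for layers in self._encoders]

    def residual_raw(self, x: Tensor) -> Tensor:
        return self._mlp(self._res_encoder, x)

    def compose_codes(self, probs: list[Tensor], labels: np.ndarray | None = None,
                      mask: np.ndarray | None = None) -> list[Tensor]:
        """Vectorized latent composition over a batch.

        Labeled cells use the one-hot row of their true category; unlabeled
        cells use the probability-weighted mixture.
        """
        codes = []
        for j, f in enumerate(self.spec.factors):
            emb = self.params[f"emb_{f.name}"]
            w = probs[j]
            if labels is not None and mask is not None:
                mj = mask[:, j].astype(np.float64)[:, None]
                onehot = np.zeros((labels.shape[0], f.n_categories))
                lab = np.clip(labels[:, j], 0, f.n_categories - 1)
                onehot[np.arange(labels.shape[0]), lab] = 1.0
                w = w * Tensor(1.0 - mj) + Tensor(onehot * mj)
            codes.append(w @ emb)
        return codes

    def decode_tensors(self, codes: list[Tensor], residual: Tensor):
        z = concat(list(codes) + [residual], axis=1)
        h = self._mlp(self._decoder, z, final_linear=False)
        if self.config.reconstruction == "mse":
            return {"xhat": self._mlp(self._heads["out"], h)}
        mu = self._mlp(self._heads["mu"], h).softplus() + 1e-6
        theta = self._mlp(self._heads["theta"], h).softplus() + 1e-6
        return {"mu": mu, "theta": theta}

    def forward(self, X: np.ndarray, labels: np.ndarray | None = None,
                mask: np.ndarray | None = None, training: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        """Full pass over a batch; returns tensors for loss construction."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_genes:
            raise ValueError(
                f"input has {X.shape[1]} genes, model expects {self.n_genes}")
        xt = Tensor(X)
        logits = self.encoder_logits(xt)
        probs = [l.softmax(axis=1) for l in logits]
        residual = self.residual_raw(xt)
        if training:
            if rng is None:
                rng = np.random.default_rng()
            noise = rng.standard_normal(residual.shape)
            residual_used = residual + Tensor(noise)
        else:
            residual_used = residual
        codes = self.compose_codes(probs, labels, mask)
        out = self.decode_tensors(codes, residual_used)
        return {
            "logits": logits,
            "probs": probs,
            "codes": codes,
            "residual": residual,
            "residual_used": residual_used,
            "recon": out,
        }


# ---------------------------------------------------------------------------
# Public functional API
# ---------------------------------------------------------------------------


def encode(model: SCDRLModel, x: np.ndarray, training: bool = False,
           rng: np.random.Generator | None = None) -> LatentCode:
    """Encode one expression vector (or a batch) into a LatentCode."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    out = model.forward(np.atleast_2d(x), training=training, rng=rng)

    def _np(t):
        a = t.data
        return a[0] if squeeze else a

    residual = _np(out["residual"])
    noised = _np(out["residual_used"]) if training else None
    return LatentCode(
        logits=[_np(t) for t in out["logits"]],
        probs=[_np(t) for t in out["probs"]],
        codes=[_np(t) for t in out["codes"]],
        residual=residual,
        residual_noised=noised,
    )


def decode(model: SCDRLModel, codes: list[np.ndarray], residual: np.ndarray):
    """Decode factor codes + residual; returns xhat (mse) or (mu, theta) (nb)."""
    squeeze = np.asarray(residual).ndim == 1
    ct = [Tensor(np.atleast_2d(np.asarray(c, dtype=np.float64))) for c in codes]
    rt = Tensor(np.atleast_2d(np.asarray(residual, dtype=np.float64)))
    for c, f in zip(ct, model.spec.factors):
        if c.shape[1] != f.code_dim:
            raise ValueError(f"code dim mismatch for factor {f.name!r}")
    if rt.shape[1] != model.spec.residual_dim:
        raise ValueError("residual dim mismatch")
    out = model.decode_tensors(ct, rt)

    def _np(t):
        return t.data[0] if squeeze else t.data

    if model.config.reconstruction == "mse":
        return _np(out["xhat"])
    return _np(out["mu"]), _np(out["theta"])


def save_model(model: SCDRLModel, path: str) -> None:
    """Save weights + config into one self-describing .npz archive."""
    arrays = {name: t.data for name, t in model.params.items()}
    meta = json.dumps({"n_genes": model.n_genes, "config": model.config.to_dict()})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_model(path: str, expected_spec: FactorSpec | None = None) -> SCDRLModel:
    """Load an archive; optionally validate the factor spec before inference."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        config = ModelConfig.from_dict(meta["config"])
        if expected_spec is not None and config.spec != expected_spec:
            raise ValueError("checkpoint factor spec does not match expected spec")
        model = SCDRLModel(meta["n_genes"], config)
        for name, t in model.params.items():
            data = npz[name]
            if data.shape != t.data.shape:
                raise ValueError(f"weight shape mismatch for {name}")
            t.data = data.astype(np.float64)
    return model
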