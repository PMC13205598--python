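"""Dual adversarial autoencoder for sequences of set-valued medical records.

Patients are encoded as padded sequences of multi-hot visit vectors over a
token vocabulary of diagnosis codes, age-band tokens, sex tokens and an
end-of-sequence token.  A single-hidden-layer visit-set embedder feeds a GRU
sequence encoder whose final state maps to a latent code; a GRU decoder
(conditioned on the latent code at every step) emits per-visit token
probabilities.  Two critics make the model *dual* adversarial: a latent
critic pushes encoder outputs toward the standard normal prior, and a data
critic discriminates pooled real visit profiles from generated ones.

Training runs a fixed number of epochs with no early stopping.  The
reconstruction optimizer optionally applies differentially private updates
(per-sample gradient clipping plus Gaussian noise, DP-Adam style); no formal
(epsilon, delta) accountant is implemented — the noise multiplier, clip norm
and step count are reported for informal accounting only.

The module follows a model/results split: ``DAAEModel(cohort, config).fit()``
returns a :class:`DAAEResults` carrying the learned parameters, the per-epoch
loss traces and the sampling interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._autodiff import Adam, Tensor, bce_with_logits
from .records import FEMALE, MALE, Cohort, PatientRecord, Visit

__all__ = ["DAAEConfig", "TokenVocab", "DAAEModel", "DAAEResults", "encode_cohort"]


@dataclass(frozen=True)
class DAAEConfig:
    latent_dim: int = 8
    gru_hidden: int = 64
    embed_dim: int = 64
    critic_hidden: int = 32
    batch_size: int = 256
    epochs: int = 50  # desk-scale default; full-scale runs used 500
    l2_weight: float = 1e-5
    learning_rate: float = 1e-2
    # weight on active tokens in the reconstruction loss; visit vectors are
    # sparse (a few active tokens out of hundreds), so unweighted BCE drives
    # every probability below the 0.5 activation threshold
    pos_weight: float = 8.0
    adv_latent_weight: float = 1.0
    adv_data_weight: float = 0.1
    # moment-matching penalty pushing batch latent mean/variance toward the
    # standard normal prior; stabilizes the latent critic at small batch counts
    latent_moment_weight: float = 1.0
    # SD of Gaussian noise added to the latent code during reconstruction;
    # widens each record's latent basin so prior draws decode cleanly
    latent_noise_sd: float = 0.3
    dp_enabled: bool = False
    dp_clip_norm: Optional[float] = None
    dp_noise_multiplier: Optional[float] = None
    age_band_width: float = 5.0  # years; 1.0 at full scale
    max_len: int = 32  # visit slots incl. the end-of-sequence slot
    seed: int = 0

    def __post_init__(self):
        if min(self.latent_dim, self.gru_hidden, self.embed_dim, self.max_len) <= 0:
            raise ValueError("model dimensions must be positive")
        if self.dp_enabled and (self.dp_clip_norm is None or self.dp_noise_multiplier is None):
            raise ValueError("dp_clip_norm and dp_noise_multiplier required when dp_enabled")
        if not self.dp_enabled and (
            self.dp_clip_norm is not None or self.dp_noise_multiplier is not None
        ):
            raise ValueError("dp fields are only valid when dp_enabled")


class TokenVocab:
    """codes + age-band tokens + sex tokens + end-of-sequence token."""

    def __init__(self, codes, age_band_width: float, max_age: float = 100.0):
        self.codes = tuple(codes)
        self.width = float(age_band_width)
        self.n_bands = int(max_age // self.width) + 1
        self.tokens = (
            list(self.codes)
            + [f"AGE{k}" for k in range(self.n_bands)]
            + ["SEX_F", "SEX_M", "EOS"]
        )
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.n_codes = len(self.codes)
        self.size = len(self.tokens)
        self.age_offset = self.n_codes
        self.i_sex_f = self.index["SEX_F"]
        self.i_sex_m = self.index["SEX_M"]
        self.i_eos = self.index["EOS"]

    def age_band(self, age: float) -> int:
        return min(int(age // self.width), self.n_bands - 1)

    def band_midpoint(self, band: int) -> float:
        return round(band * self.width + self.width / 2.0, 1)


def encode_cohort(cohort: Cohort, config: DAAEConfig):
    """Encode a cohort into (X, mask): X is [n, L, vocab] multi-hot visit
    vectors (one age-band token per aged visit, sex token prepended into the
    first visit, an end-of-sequence step appended); mask is [n, L].
    Truncation keeps the earliest-age visits within L - 1 content slots."""
    vocab = TokenVocab(cohort.vocabulary, config.age_band_width)
    unknown = set()
    for r in cohort.records:
        unknown |= r.codes() - set(cohort.vocabulary)
    if unknown:
        raise ValueError(f"codes outside the vocabulary: {sorted(unknown)}")
    n, L, V = len(cohort.records), config.max_len, vocab.size
    X = np.zeros((n, L, V), dtype=np.float64)
    mask = np.zeros((n, L), dtype=np.float64)
    for i, r in enumerate(cohort.records):
        visits = r.visits[: L - 1]
        for t, v in enumerate(visits):
            for c in v.codes:
                X[i, t, vocab.index[c]] = 1.0
            age = v.effective_age
            if age is not None:
                X[i, t, vocab.age_offset + vocab.age_band(age)] = 1.0
            if t == 0 and r.sex in (FEMALE, MALE):
                X[i, t, vocab.i_sex_f if r.sex == FEMALE else vocab.i_sex_m] = 1.0
        t_eos = len(visits)
        X[i, t_eos, vocab.i_eos] = 1.0
        mask[i, : t_eos + 1] = 1.0
    return X, mask, vocab


def _init(rng: np.random.Generator, *shape) -> Tensor:
    scale = 1.0 / np.sqrt(shape[0]) if len(shape) > 1 else 0.0
    return Tensor.param(rng.normal(0.0, max(scale, 1e-8), size=shape) if scale else np.zeros(shape))


def _gru_params(rng, dins, h, prefix):
    """GRU parameters with one input matrix per input stream in ``dins``."""
    out = {}
    for gate in ("z", "r", "h"):
        for k, din in enumerate(dins):
            out[f"{prefix}_W{k}{gate}"] = _init(rng, din, h)
        out[f"{prefix}_U{gate}"] = _init(rng, h, h)
        out[f"{prefix}_b{gate}"] = Tensor.param(np.zeros(h))
    return out


def _gru_step(p, prefix, xs, h):
    def pre(gate, hin):
        acc = hin @ p[f"{prefix}_U{gate}"] + p[f"{prefix}_b{gate}"]
        for k, x in enumerate(xs):
            acc = acc + x @ p[f"{prefix}_W{k}{gate}"]
        return acc

    z = pre("z", h).sigmoid()
    r = pre("r", h).sigmoid()
    hh = pre("h", r * h).tanh()  # candidate state uses the reset-gated hidden
    one = Tensor(np.ones(1))
    return (one - z) * hh + z * h


def _mlp(p, prefix, x):
    h1 = (x @ p[f"{prefix}_W1"] + p[f"{prefix}_b1"]).relu()
    h2 = (h1 @ p[f"{prefix}_W2"] + p[f"{prefix}_b2"]).relu()
    return h2 @ p[f"{prefix}_W3"] + p[f"{prefix}_b3"]


class DAAEModel:
    """Unfitted dual adversarial autoencoder bound to a training cohort."""

    def __init__(self, cohort: Cohort, config: DAAEConfig = DAAEConfig()):
        self.cohort = cohort
        self.config = config
        self.X, self.mask, self.vocab = encode_cohort(cohort, config)

    # -- parameter set ---------------------------------------------------
    def _init_params(self, rng) -> dict:
        c, V = self.config, self.vocab.size
        p = {}
        p["emb_W"] = _init(rng, V, c.embed_dim)
        p["emb_b"] = Tensor.param(np.zeros(c.embed_dim))
        p.update(_gru_params(rng, (c.embed_dim,), c.gru_hidden, "enc"))
        p["mu_W"] = _init(rng, c.gru_hidden, c.latent_dim)
        p["mu_b"] = Tensor.param(np.zeros(c.latent_dim))
        p["zh_W"] = _init(rng, c.latent_dim, c.gru_hidden)
        p["zh_b"] = Tensor.param(np.zeros(c.gru_hidden))
        # decoder GRU consumes the embedded previous visit plus the latent code
        p.update(_gru_params(rng, (c.embed_dim, c.latent_dim), c.gru_hidden, "dec"))
        p["out_W"] = _init(rng, c.gru_hidden, V)
        p["out_b"] = Tensor.param(np.zeros(V))
        for prefix, din in (("lc", c.latent_dim), ("dc", V)):
            p[f"{prefix}_W1"] = _init(rng, din, c.critic_hidden)
            p[f"{prefix}_b1"] = Tensor.param(np.zeros(c.critic_hidden))
            p[f"{prefix}_W2"] = _init(rng, c.critic_hidden, c.critic_hidden)
            p[f"{prefix}_b2"] = Tensor.param(np.zeros(c.critic_hidden))
            p[f"{prefix}_W3"] = _init(rng, c.critic_hidden, 1)
            p[f"{prefix}_b3"] = Tensor.param(np.zeros(1))
        return p

    @staticmethod
    def _group(p, prefixes):
        return [v for k, v in p.items() if any(k.startswith(q) for q in prefixes)]

    # -- forward pieces ---------------------------------------------------
    def _encode(self, p, X, mask):
        B, L, _ = X.shape
        h = Tensor(np.zeros((B, self.config.gru_hidden)))
        for t in range(L):
            e = (Tensor(X[:, t, :]) @ p["emb_W"] + p["emb_b"]).relu()
            h_new = _gru_step(p, "enc", (e,), h)
            m = Tensor(mask[:, t][:, None])
            one = Tensor(np.ones(1))
            h = m * h_new + (one - m) * h
        return h @ p["mu_W"] + p["mu_b"]

    def _decode_logits(self, p, z, L, teacher: Optional[np.ndarray] = None,
                       feedback: str = "soft"):
        """Autoregressive decoder: each step consumes the embedded previous
        visit plus the latent code.  ``teacher`` supplies ground-truth visit
        vectors (teacher forcing); otherwise the previous output is fed back,
        differentiably ("soft", sigmoid probabilities) or thresholded
        ("hard", generation)."""
        B = z.data.shape[0] if isinstance(z, Tensor) else z.shape[0]
        zt = z if isinstance(z, Tensor) else Tensor(z)
        h = (zt @ p["zh_W"] + p["zh_b"]).tanh()
        V = p["out_b"].data.shape[0]
        prev: Tensor = Tensor(np.zeros((B, V)))
        logits = []
        for t in range(L):
            e = (prev @ p["emb_W"] + p["emb_b"]).relu()
            h = _gru_step(p, "dec", (e, zt), h)
            lt = h @ p["out_W"] + p["out_b"]
            logits.append(lt)
            if teacher is not None:
                prev = Tensor(teacher[:, t, :])
            elif feedback == "soft":
                prev = lt.sigmoid()
            else:
                prev = Tensor((lt.data >= 0.0).astype(np.float64))  # prob >= .5
        return logits

    def _recon_loss(self, p, X, mask, rng=None):
        B, L, V = X.shape
        z = self._encode(p, X, mask)
        z_dec = z
        if rng is not None and self.config.latent_noise_sd > 0:
            noise = rng.normal(0.0, self.config.latent_noise_sd, size=z.data.shape)
            z_dec = z + Tensor(noise)
        logits = self._decode_logits(p, z_dec, L, teacher=X)
        loss = None
        pw = self.config.pos_weight
        wmat = 1.0 + (pw - 1.0) * X  # [B, L, V]
        total_w = float((wmat * mask[:, :, None]).sum())
        for t in range(L):
            w = wmat[:, t, :] * mask[:, t][:, None]
            wt = w.sum()
            if wt == 0:
                continue
            step = bce_with_logits(logits[t], X[:, t, :], w) * float(wt / total_w)
            loss = step if loss is None else loss + step
        lam = self.config.latent_moment_weight
        if lam > 0:
            ones = Tensor(np.full((1, B), 1.0 / B))
            mu = ones @ z
            cent = z + (-1.0) * mu
            var = ones @ (cent * cent)
            vdev = var + Tensor(-np.ones_like(var.data))
            loss = loss + ((mu * mu).mean() + (vdev * vdev).mean()) * lam
        return loss, z

    # -- training ---------------------------------------------------------
    def fit(self) -> "DAAEResults":
        c = self.config
        rng = np.random.default_rng(c.seed)
        p = self._init_params(rng)
        n = len(self.cohort.records)
        if n == 0:
            raise ValueError("cannot train on an empty cohort")
        ae_params = self._group(p, ("emb_", "enc_", "mu_", "zh_", "dec_", "out_"))
        enc_params = self._group(p, ("emb_", "enc_", "mu_"))
        dec_params = self._group(p, ("zh_", "dec_", "out_"))
        lc_params = self._group(p, ("lc_",))
        dc_params = self._group(p, ("dc_",))
        opt_ae = Adam(ae_params, lr=c.learning_rate)
        opt_enc = Adam(enc_params, lr=c.learning_rate)
        opt_dec = Adam(dec_params, lr=c.learning_rate)
        opt_lc = Adam(lc_params, lr=c.learning_rate)
        opt_dc = Adam(dc_params, lr=c.learning_rate)
        trace = {"reconstruction": [], "adversarial_latent": [], "adversarial_data": []}

        def _check(val, epoch, component):
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite {component} loss at epoch {epoch + 1}")

        for epoch in range(c.epochs):
            order = rng.permutation(n)
            ep = {k: [] for k in trace}
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                Xb, mb = self.X[idx], self.mask[idx]
                B = len(idx)

                # (a) reconstruction
                if c.dp_enabled:
                    loss_val = self._dp_recon_step(p, ae_params, opt_ae, Xb, mb, rng)
                else:
                    for q in ae_params:
                        q.grad = None
                    loss, _ = self._recon_loss(p, Xb, mb, rng)
                    loss.backward()
                    self._apply_l2(ae_params)
                    opt_ae.step()
                    loss_val = float(loss.data)
                _check(loss_val, epoch, "reconstruction")
                ep["reconstruction"].append(loss_val)

                # (b) latent critic, then encoder adversarial
                if c.adv_latent_weight > 0:
                    z_enc = self._encode(p, Xb, mb).detach()
                    z_prior = Tensor(rng.standard_normal((B, c.latent_dim)))
                    for q in lc_params:
                        q.grad = None
                    lc_loss = bce_with_logits(
                        _mlp(p, "lc", z_prior), np.ones((B, 1))
                    ) + bce_with_logits(_mlp(p, "lc", z_enc), np.zeros((B, 1)))
                    lc_loss.backward()
                    opt_lc.step()

                    for q in enc_params + lc_params:
                        q.grad = None
                    z_enc2 = self._encode(p, Xb, mb)
                    adv_l = bce_with_logits(_mlp(p, "lc", z_enc2), np.ones((B, 1)))
                    scaled = adv_l * c.adv_latent_weight
                    scaled.backward()
                    opt_enc.step()  # critic grads discarded: only encoder moves
                    _check(float(adv_l.data), epoch, "adversarial-latent")
                    ep["adversarial_latent"].append(float(adv_l.data))
                else:
                    ep["adversarial_latent"].append(0.0)

                # (c) data critic, then decoder adversarial
                if c.adv_data_weight > 0:
                    pooled_real = Tensor(Xb.mean(axis=1))
                    z_p = Tensor(rng.standard_normal((B, c.latent_dim)))
                    gen_logits = self._decode_logits(p, z_p, c.max_len)
                    pooled = None
                    for lt in gen_logits:
                        s = lt.sigmoid()
                        pooled = s if pooled is None else pooled + s
                    pooled_gen = pooled * (1.0 / c.max_len)
                    for q in dc_params:
                        q.grad = None
                    dc_loss = bce_with_logits(
                        _mlp(p, "dc", pooled_real), np.ones((B, 1))
                    ) + bce_with_logits(
                        _mlp(p, "dc", pooled_gen.detach()), np.zeros((B, 1))
                    )
                    dc_loss.backward()
                    opt_dc.step()

                    for q in dec_params + dc_params:
                        q.grad = None
                    z_p2 = Tensor(rng.standard_normal((B, c.latent_dim)))
                    gen2 = self._decode_logits(p, z_p2, c.max_len)
                    pooled2 = None
                    for lt in gen2:
                        s = lt.sigmoid()
                        pooled2 = s if pooled2 is None else pooled2 + s
                    adv_d = bce_with_logits(
                        _mlp(p, "dc", pooled2 * (1.0 / c.max_len)), np.ones((B, 1))
                    )
                    scaled = adv_d * c.adv_data_weight
                    scaled.backward()
                    opt_dec.step()
                    _check(float(adv_d.data), epoch, "adversarial-data")
                    ep["adversarial_data"].append(float(adv_d.data))
                else:
                    ep["adversarial_data"].append(0.0)
            for k in trace:
                trace[k].append(float(np.mean(ep[k])))
        return DAAEResults(model=self, params=p, loss_trace=trace)

    def _apply_l2(self, params):
        if self.config.l2_weight:
            for q in params:
                if q.grad is not None:
                    q.grad = q.grad + 2.0 * self.config.l2_weight * q.data

    def _dp_recon_step(self, p, ae_params, opt_ae, Xb, mb, rng) -> float:
        """Per-sample clipped, noised reconstruction update (DP-Adam style)."""
        c = self.config
        B = len(Xb)
        acc = [np.zeros_like(q.data) for q in ae_params]
        vals = []
        for i in range(B):
            for q in ae_params:
                q.grad = None
            loss, _ = self._recon_loss(p, Xb[i : i + 1], mb[i : i + 1], rng)
            loss.backward()
            vals.append(float(loss.data))
            grads = [
                q.grad if q.grad is not None else np.zeros_like(q.data)
                for q in ae_params
            ]
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
            scale = min(1.0, c.dp_clip_norm / norm) if norm > 0 else 1.0
            for a, g in zip(acc, grads):
                a += g * scale
        sigma = c.dp_noise_multiplier * c.dp_clip_norm
        final = [
            (a + rng.normal(0.0, sigma, size=a.shape)) / B
            + 2.0 * c.l2_weight * q.data
            for a, q in zip(acc, ae_params)
        ]
        opt_ae.step(grads=final)
        return float(np.mean(vals))


@dataclass
class DAAEResults:
    """Fitted generator: parameters, loss traces, sampling and reconstruction."""

    model: DAAEModel
    params: dict
    loss_trace: dict = field(default_factory=dict)

    @property
    def config(self) -> DAAEConfig:
        return self.model.config

    @property
    def vocab(self) -> TokenVocab:
        return self.model.vocab

    # -- generation -------------------------------------------------------
    def _decode_to_records(self, z: np.ndarray, id_prefix: str):
        p, c, vocab = self.params, self.config, self.vocab
        zt = Tensor(z)
        logits = self._np_logits(zt)
        records = []
        for i in range(len(z)):
            visits = []
            sex = None
            for t in range(c.max_len):
                probs = logits[t][i]
                active = np.flatnonzero(probs >= 0.5)
                if vocab.i_eos in active:
                    break
                codes = [vocab.tokens[a] for a in active if a < vocab.n_codes]
                bands = [
                    a - vocab.age_offset
                    for a in active
                    if vocab.age_offset <= a < vocab.age_offset + vocab.n_bands
                ]
                if t == 0:
                    pf, pm = probs[vocab.i_sex_f], probs[vocab.i_sex_m]
                    if pf >= 0.5 or pm >= 0.5:
                        sex = FEMALE if pf >= pm else MALE
                ages = tuple(vocab.band_midpoint(b) for b in sorted(bands))
                visits.append(Visit(codes=frozenset(codes), ages=ages))
            records.append(
                PatientRecord(id=f"{id_prefix}{i:06d}", sex=sex, visits=tuple(visits))
            )
        return records

    def _np_logits(self, z: Tensor):
        """Deterministic generation pass (hard feedback), probabilities per step."""
        p, c = self.params, self.config
        logits = self.model._decode_logits(p, z, c.max_len, feedback="hard")
        sig = [1.0 / (1.0 + np.exp(-np.clip(lt.data, -60, 60))) for lt in logits]
        return sig

    def sample(self, n: int, seed: int = 0) -> Cohort:
        """Draw ``n`` raw synthetic records from the prior; the output may
        contain every defect the refinement pipeline handles."""
        if n < 0:
            raise ValueError("n must be non-negative")
        rng = np.random.default_rng(seed)
        if n == 0:
            return self.model.cohort.with_records(())
        z = rng.standard_normal((n, self.config.latent_dim))
        records = self._decode_to_records(z, "g")
        return Cohort(
            records=tuple(records),
            vocabulary=self.model.cohort.vocabulary,
            anchor_code=self.model.cohort.anchor_code,
            endpoint_code=self.model.cohort.endpoint_code,
        )

    def reconstruct(self, cohort: Cohort) -> Cohort:
        """Deterministic encode-then-decode round trip of a cohort."""
        unknown = set(cohort.vocabulary) - set(self.model.cohort.vocabulary)
        if unknown:
            raise ValueError(f"codes outside the generator vocabulary: {sorted(unknown)}")
        cohort = Cohort(
            records=cohort.records,
            vocabulary=self.model.cohort.vocabulary,
            anchor_code=cohort.anchor_code,
            endpoint_code=cohort.endpoint_code,
        )
        X, mask, _ = encode_cohort(cohort, self.config)
        z = self.model._encode(self.params, X, mask)
        records = self._decode_to_records(z.data, "r")
        records = [
            PatientRecord(id=orig.id, sex=rec.sex, visits=rec.visits,
                          diagnosis_year=orig.diagnosis_year)
            for orig, rec in zip(cohort.records, records)
        ]
        return cohort.with_records(records)

    # -- reporting / persistence ------------------------------------------
    def summary(self) -> str:
        c = self.config
        lines = [
            "Dual adversarial autoencoder (fitted)",
            f"  vocabulary: {self.vocab.size} tokens "
            f"({self.vocab.n_codes} codes, {self.vocab.n_bands} age bands)",
            f"  latent dim {c.latent_dim}, GRU hidden {c.gru_hidden}, "
            f"max length {c.max_len}",
            f"  epochs {c.epochs}, batch {c.batch_size}, lr {c.learning_rate}, "
            f"DP {'on' if c.dp_enabled else 'off'}",
        ]
        if self.loss_trace.get("reconstruction"):
            tr = self.loss_trace
            lines.append(
                f"  final losses: recon {tr['reconstruction'][-1]:.4f}, "
                f"adv-latent {tr['adversarial_latent'][-1]:.4f}, "
                f"adv-data {tr['adversarial_data'][-1]:.4f}"
            )
        if c.dp_enabled:
            steps = len(self.loss_trace.get("reconstruction", [])) or c.epochs
            lines.append(
                f"  DP accounting (informal): clip {c.dp_clip_norm}, "
                f"noise multiplier {c.dp_noise_multiplier}, ~{steps} epochs of steps"
            )
        return "\n".join(lines)

    def save(self, path, config_path=None) -> None:
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump(
                    {
                        "config": {
                            k: getattr(self.config, k)
                            for k in self.config.__dataclass_fields__
                        },
                        "loss_trace": self.loss_trace,
                    },
                    fh,
                )

    def loss_trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.loss_trace)
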