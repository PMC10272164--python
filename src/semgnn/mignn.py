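"""Molecular-interaction graph neural network (MIGNN) and the GCN control.

Architecture, per target-property channel (steric and electronic are
processed by separate weight stacks of identical layout):

1. masked self-attention over each molecule's atoms (``atom_attention``
   layers) on the flattened per-atom encoding;
2. ``linear_depth`` linear layers, each followed by batch normalization
   and tanh; the last maps back to the encoding's spatial grid;
3. per-atom convolution over the spatial grid (2-D for the 10 x 20 steric
   map, 3-D for the 7 x 7 x 7 electronic tensor), max-pooling over each
   molecule's real atoms (padded atoms enter as -inf), concatenation of
   the m component molecules along the channel axis — role order is
   therefore information-bearing — then a second strided convolution
   (steric) or a spatial max-pool (electronic) and flattening into the
   one-dimensional reaction vector;
4. interaction module: attention + one linear layer compress the reaction
   vector to a representation u, the rank-one interaction matrix u u^T
   lets every component's information multiply every other's, and three
   convolutions + flatten give the interaction vector;
5. head: the steric/electronic reaction vectors and both interaction
   vectors are concatenated, one attention layer weighs the four blocks,
   and three linear layers emit the scalar prediction.

The GCN control shares the featurization but uses plain neighborhood
convolutions with mean pooling and no interaction module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .chemio import ReactionRecord
from .electronic import ElectronicConfig
from .errors import AssemblyError, CapabilityError, ValidationError
from .semg import build_baseline, encode_molecule, pad_batch
from .steric import StericConfig

STERIC_SCALE = 0.1  # maps 0-10 A distances into [0, 1]


@dataclass
class ModelConfig:
    """Hyper-parameters of the MIGNN / GCN models.

    ``atom_attention``, ``linear_depth`` and ``inter_attention`` are the
    stack depths named in the architecture; the remaining widths are
    desk-scale defaults exposed for tuning.  ``seed`` fixes every weight
    initialization; ``interaction=False`` ablates the interaction module
    (the head then sees only the two reaction vectors).
    """

    atom_attention: int = 1
    linear_depth: int = 2
    inter_attention: int = 1
    hidden_width: int = 48
    conv_channels: int = 4
    d_key: int = 16
    u_dim: int = 16
    head_token_width: int = 48
    interaction: bool = True
    seed: int = 0
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"  # or "step": lr x0.3 after 70% of epochs
    epochs: int = 60
    batch_size: int = 50

    def __post_init__(self) -> None:
        if min(self.atom_attention, self.linear_depth, self.inter_attention) < 1:
            raise ValidationError("all depths must be >= 1")


# ---------------------------------------------------------------------------
# featurization: records -> padded reaction tensors
# ---------------------------------------------------------------------------

_ENCODING_CACHE: dict = {}


def clear_encoding_cache() -> None:
    _ENCODING_CACHE.clear()


def _encoding_key(mol, steric_cfg: StericConfig, electronic_cfg: ElectronicConfig):
    tag = mol.provenance or id(mol)
    return (tag, steric_cfg.radius, steric_cfg.n_polar, electronic_cfg.backend)


def featurize_records(
    records: list[ReactionRecord],
    steric_cfg: StericConfig | None = None,
    electronic_cfg: ElectronicConfig | None = None,
    max_atoms: int | None = None,
    graph_kind: str = "semg",
) -> dict:
    """Build padded per-reaction tensors from reaction records.

    Returns a dict with ``mask`` (B, m, A) and either ``steric`` /
    ``electronic`` stacks (SEMG) or ``features`` + ``adjacency`` (baseline
    graphs), plus ``targets``, ``roles`` and ``max_atoms``.  Molecule
    encodings are cached by provenance, so shared library molecules are
    encoded once per configuration.
    """
    if not records:
        raise ValidationError("no records to featurize")
    steric_cfg = steric_cfg or StericConfig()
    electronic_cfg = electronic_cfg or ElectronicConfig()
    roles = records[0].roles
    for rec in records:
        if rec.roles != roles:
            raise AssemblyError("records disagree on component role order")
    graphs_per_record = []
    for rec in records:
        graphs = []
        for mol in rec.molecules:
            if graph_kind == "semg":
                key = _encoding_key(mol, steric_cfg, electronic_cfg)
                if key not in _ENCODING_CACHE:
                    _ENCODING_CACHE[key] = encode_molecule(
                        mol, steric_cfg, electronic_cfg
                    )
                graphs.append(_ENCODING_CACHE[key])
            else:
                graphs.append(build_baseline(mol))
        graphs_per_record.append(graphs)
    if max_atoms is None:
        max_atoms = max(g.n_atoms for gs in graphs_per_record for g in gs)
    m = len(roles)
    batches = [pad_batch(gs, max_atoms) for gs in graphs_per_record]
    out: dict = {
        "mask": np.stack([b["mask"] for b in batches]),
        "roles": roles,
        "max_atoms": max_atoms,
        "targets": np.array([r.target for r in records], dtype=np.float64),
        "graph_kind": graph_kind,
    }
    if graph_kind == "semg":
        out["steric"] = (
            np.stack([b["steric"] for b in batches]) * STERIC_SCALE
        ).astype(np.float32)
        out["electronic"] = np.stack([b["electronic"] for b in batches]).astype(
            np.float32
        )
    else:
        out["features"] = np.stack([b["features"] for b in batches]).astype(np.float32)
        out["adjacency"] = np.stack([b["adjacency"] for b in batches]).astype(
            np.float32
        )
    return out


def slice_features(feats: dict, idx: np.ndarray) -> dict:
    out = dict(feats)
    for key in ("mask", "steric", "electronic", "features", "adjacency", "targets"):
        if key in feats:
            out[key] = feats[key][idx]
    return out


# ---------------------------------------------------------------------------
# MIGNN
# ---------------------------------------------------------------------------

class _ChannelEncoder(nn.Module):
    """Attention -> linear/BN/tanh -> per-atom conv -> pooled reaction vector."""

    def __init__(self, spatial: tuple[int, ...], m: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        d = int(np.prod(spatial))
        h = cfg.hidden_width
        c = cfg.conv_channels
        self.spatial = spatial
        self.m = m
        self.cfg = cfg
        self.attn = [
            nn.SelfAttention(d if i == 0 else h, h, rng, d_key=cfg.d_key)
            for i in range(cfg.atom_attention)
        ]
        self.linears = [
            nn.Linear(h, h if i < cfg.linear_depth - 1 else d, rng)
            for i in range(cfg.linear_depth)
        ]
        self.norms = [
            nn.BatchNorm(h if i < cfg.linear_depth - 1 else d)
            for i in range(cfg.linear_depth)
        ]
        k_elem = 3 ** len(spatial)
        self.plan = nn.GridConvPlan(spatial, c, kernel=3, stride=1, padding=1)
        self.w1 = nn.glorot(rng, k_elem, k_elem * c, (c, *([3] * len(spatial))))
        self.b1 = nn.Tensor(np.zeros(c, dtype=nn.DEFAULT_DTYPE), requires_grad=True)
        if len(spatial) == 2:
            self.w2 = nn.glorot(rng, m * c * 9, c * 9, (c, m * c, 3, 3))
            self.b2 = nn.Tensor(np.zeros(c, dtype=nn.DEFAULT_DTYPE), requires_grad=True)
            self.out_len = c * (spatial[0] // 2) * (spatial[1] // 2)
        else:
            self.out_len = m * c * (spatial[0] // 2) * (spatial[1] // 2) * (spatial[2] // 2)

    def __call__(self, x_np: np.ndarray, mask: np.ndarray, train: bool) -> nn.Tensor:
        B, m, A = x_np.shape[:3]
        d = int(np.prod(self.spatial))
        x = nn.Tensor(x_np.reshape(B * m, A, d).astype(nn.DEFAULT_DTYPE))
        flat_mask = mask.reshape(B * m, A)
        for layer in self.attn:
            x = layer(x, flat_mask)
        # pack real atoms: the per-atom stack below never sees padding
        real = np.flatnonzero(flat_mask.reshape(-1))
        rows = x.reshape(B * m * A, x.shape[-1])[real]
        for lin, norm in zip(self.linears, self.norms):
            rows = norm(lin(rows), train=train).tanh()
        per_atom = nn.grid_conv(rows, self.w1, self.b1, self.plan)
        c = self.cfg.conv_channels
        per_atom = nn.scatter_rows(per_atom, real, B * m * A)
        per_atom = per_atom.reshape(B, m, A, c, *self.spatial)
        neg = np.where(mask, 0.0, -1e9).astype(nn.DEFAULT_DTYPE)
        bias = neg.reshape(B, m, A, *([1] * (1 + len(self.spatial))))
        pooled = (per_atom + nn.Tensor(bias)).amax(axis=2)  # (B, m, c, *spatial)
        stacked = pooled.reshape(B, m * c, *self.spatial)
        if len(self.spatial) == 2:
            out = nn.conv2d(stacked, self.w2, self.b2, stride=2, padding=1).tanh()
        else:
            out = nn.maxpool3d(stacked, 2)
        return out.reshape(B, self.out_len)


class _InteractionModule(nn.Module):
    """u = attn+linear(v); M = u u^T; three convolutions -> interaction vector."""

    def __init__(self, in_len: int, cfg: ModelConfig, rng: np.random.Generator):
        # token count: the largest small divisor of the vector length
        self.n_tokens = next(t for t in (8, 6, 4, 3, 2, 1) if in_len % t == 0)
        d_tok = in_len // self.n_tokens
        self.attn = [
            nn.SelfAttention(d_tok, d_tok, rng, d_key=cfg.d_key)
            for _ in range(cfg.inter_attention)
        ]
        self.to_u = nn.Linear(in_len, cfg.u_dim, rng)
        c = cfg.conv_channels
        self.w1 = nn.glorot(rng, 9, 9 * c, (c, 1, 3, 3))
        self.b1 = nn.Tensor(np.zeros(c, dtype=nn.DEFAULT_DTYPE), requires_grad=True)
        self.w2 = nn.glorot(rng, 9 * c, 9 * c, (c, c, 3, 3))
        self.b2 = nn.Tensor(np.zeros(c, dtype=nn.DEFAULT_DTYPE), requires_grad=True)
        self.w3 = nn.glorot(rng, 9 * c, 9, (1, c, 3, 3))
        self.b3 = nn.Tensor(np.zeros(1, dtype=nn.DEFAULT_DTYPE), requires_grad=True)
        self.u_dim = cfg.u_dim
        self.out_len = cfg.u_dim * cfg.u_dim
        self.last_matrix: np.ndarray | None = None

    def __call__(self, v: nn.Tensor, train: bool) -> nn.Tensor:
        B, L = v.shape
        tokens = v.reshape(B, self.n_tokens, L // self.n_tokens)
        for layer in self.attn:
            tokens = layer(tokens)
        u = self.to_u(tokens.reshape(B, L))  # (B, u_dim)
        m = u.reshape(B, self.u_dim, 1) @ u.reshape(B, 1, self.u_dim)
        self.last_matrix = m.data
        x = m.reshape(B, 1, self.u_dim, self.u_dim)
        x = nn.conv2d(x, self.w1, self.b1, padding=1).tanh()
        x = nn.conv2d(x, self.w2, self.b2, padding=1).tanh()
        x = nn.conv2d(x, self.w3, self.b3, padding=1)
        return x.reshape(B, self.out_len)


class MIGNN(nn.Module):
    """Two-channel interaction GNN over padded reaction tensors.

    Construct with the dataset geometry (number of component molecules m,
    max atom count A, spatial encoding shapes) and a :class:`ModelConfig`;
    call :meth:`forward` with a featurized batch.
    """

    def __init__(
        self,
        m: int,
        max_atoms: int,
        cfg: ModelConfig,
        steric_shape: tuple[int, int] = (10, 20),
        electronic_shape: tuple[int, int, int] = (7, 7, 7),
    ):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.m = m
        self.max_atoms = max_atoms
        self.steric_enc = _ChannelEncoder(steric_shape, m, cfg, rng)
        self.elec_enc = _ChannelEncoder(electronic_shape, m, cfg, rng)
        if cfg.interaction:
            self.steric_inter = _InteractionModule(self.steric_enc.out_len, cfg, rng)
            self.elec_inter = _InteractionModule(self.elec_enc.out_len, cfg, rng)
        else:
            self.steric_inter = self.elec_inter = None
        blocks = [self.steric_enc.out_len, self.elec_enc.out_len]
        if cfg.interaction:
            blocks += [self.steric_inter.out_len, self.elec_inter.out_len]
        t = cfg.head_token_width
        self.block_proj = [nn.Linear(bl, t, rng) for bl in blocks]
        self.head_attn = nn.SelfAttention(t, t, rng, d_key=cfg.d_key)
        self.head1 = nn.Linear(len(blocks) * t, 64, rng)
        self.head2 = nn.Linear(64, 32, rng)
        self.head3 = nn.Linear(32, 1, rng)

    def forward(self, batch: dict, train: bool = False) -> nn.Tensor:
        """Scalar prediction per reaction (z-scored target units)."""
        vs = self.steric_enc(batch["steric"], batch["mask"], train)
        ve = self.elec_enc(batch["electronic"], batch["mask"], train)
        parts = [vs, ve]
        if self.cfg.interaction:
            parts.append(self.steric_inter(vs, train))
            parts.append(self.elec_inter(ve, train))
        tokens = nn.stack(
            [proj(p).tanh() for proj, p in zip(self.block_proj, parts)], axis=1
        )
        x = self.head_attn(tokens)
        B = x.shape[0]
        x = self.head1(x.reshape(B, -1)).tanh()
        x = self.head2(x).tanh()
        out = self.head3(x)
        if not np.all(np.isfinite(out.data)):
            raise ValidationError("NaN/Inf in forward pass (prediction head)")
        return out.reshape(B)

    def predict(self, batch: dict) -> np.ndarray:
        return np.asarray(self.forward(batch, train=False).data, dtype=np.float64)

    def attention_weights(self, batch: dict, channel: str = "steric",
                          layer: int = -1) -> np.ndarray:
        """Per-atom attention weights (B, m, A), normalized per molecule.

        Extracts the requested atom-attention layer's matrix, averages the
        weight each atom receives over the molecule's real query atoms and
        renormalizes over real atoms; padded atoms get exactly 0.
        """
        enc = self.steric_enc if channel == "steric" else self.elec_enc
        self.forward(batch, train=False)
        attn = enc.attn[layer].last_attention  # (B*m, A, A)
        mask = batch["mask"]
        B, m, A = mask.shape
        flat = mask.reshape(B * m, A)
        q = flat[:, :, None].astype(float)
        received = (attn * q).sum(axis=1) / np.maximum(q.sum(axis=1), 1.0)
        received = received * flat
        total = received.sum(axis=1, keepdims=True)
        weights = np.where(total > 0, received / np.maximum(total, 1e-12), 0.0)
        return weights.reshape(B, m, A)


# ---------------------------------------------------------------------------
# GCN control
# ---------------------------------------------------------------------------

class GCN(nn.Module):
    """Graph-convolution control: no attention, no interaction module.

    Two symmetric-normalized graph convolutions with ReLU, masked mean
    pooling per molecule, concatenation across the m components in role
    order, and a two-layer head.  Works on either baseline features or
    flattened SEMG node encodings.
    """

    def __init__(self, m: int, feature_len: int, cfg: ModelConfig,
                 hidden: int = 64):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.m = m
        self.g1 = nn.Linear(feature_len, hidden, rng)
        self.g2 = nn.Linear(hidden, hidden, rng)
        self.h1 = nn.Linear(m * hidden, 32, rng)
        self.h2 = nn.Linear(32, 1, rng)

    @staticmethod
    def _node_matrix(batch: dict) -> np.ndarray:
        if "features" in batch:
            return batch["features"]
        B, m, A = batch["mask"].shape
        s = batch["steric"].reshape(B, m, A, -1)
        e = batch["electronic"].reshape(B, m, A, -1)
        return np.concatenate([s, e], axis=-1)

    def forward(self, batch: dict, train: bool = False) -> nn.Tensor:
        feats = self._node_matrix(batch)
        mask = batch["mask"]
        B, m, A = mask.shape
        adj = batch.get("adjacency")
        if adj is None:
            adj = np.zeros((B, m, A, A))
        eye = np.eye(A)[None, None]
        a_hat = adj + eye * mask[..., None]
        deg = np.maximum(a_hat.sum(-1), 1e-9)
        dinv = 1.0 / np.sqrt(deg)
        norm = a_hat * dinv[..., :, None] * dinv[..., None, :]
        norm_t = nn.Tensor(norm.reshape(B * m, A, A).astype(nn.DEFAULT_DTYPE))
        h = nn.Tensor(feats.reshape(B * m, A, -1).astype(nn.DEFAULT_DTYPE))
        h = (norm_t @ self.g1(h)).relu()
        h = (norm_t @ self.g2(h)).relu()
        w = mask.reshape(B * m, A, 1).astype(nn.DEFAULT_DTYPE)
        pooled = (h * nn.Tensor(w)).sum(axis=1) / nn.Tensor(
            np.maximum(w.sum(axis=1), 1.0)
        )
        x = self.h1(pooled.reshape(B, -1)).relu()
        out = self.h2(x)
        return out.reshape(B)

    def predict(self, batch: dict) -> np.ndarray:
        return np.asarray(self.forward(batch, train=False).data, dtype=np.float64)

    def attention_weights(self, *args, **kwargs):
        raise CapabilityError("the GCN control has no attention layers")
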