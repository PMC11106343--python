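"""Seq2seq sentence decoders for high-gamma ECoG features.

The network has three stages:

1. **Temporal convolution** — a single conv layer with kernel (W, K) and
   stride (W, 1) over the L x K feature matrix.  Because the kernel spans all
   K electrodes and the stride equals the kernel width, this is a dense map
   of each non-overlapping W-frame block to C=100 channels, producing
   N = ceil(L / W) frames (the input is zero-padded on the right when W does
   not divide L).
2. **Encoder** — a 2-layer Transformer encoder (10 heads, width 100) or a
   bidirectional LSTM of the same output width.  A 13-unit linear head
   ("feed-forward 1") maps each encoder frame to predicted MFCCs; the head is
   a training-time regularizer only and is bypassed during decoding.
3. **Decoder** — token embedding (8 x 500), a 1-layer Transformer decoder
   (masked self-attention + cross-attention over the encoder output) or a
   unidirectional LSTM initialized from the encoder's final state, then an
   8-unit linear head ("feed-forward 2") giving token logits.

Sinusoidal positional encodings are added after the conv stage and after the
token embedding; without them the Transformer would be order-blind.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .corpus import END_TOKEN, START_TOKEN, VOCAB_SIZE
from .nn import (
    Adam,
    BiLSTM,
    Dense,
    Embedding,
    LSTM,
    Module,
    Tensor,
    TransformerDecoderLayer,
    TransformerEncoderLayer,
    causal_mask,
    dropout,
    positional_encoding,
)

MAX_TARGET_LEN = 5  # start + 3 phrase tokens + end


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults follow the published network."""

    n_electrodes: int  # K, set from the data
    conv_filters: int = 100  # C
    conv_stride: int = 12  # W (kernel is W x K, stride (W, 1))
    conv_dropout: float = 0.1
    encoder_layers: int = 2  # X
    encoder_heads: int = 10
    encoder_hidden: int = 100
    encoder_dropout: float = 0.5
    mfcc_head_units: int = 13
    embed_dim: int = 500
    decoder_layers: int = 1  # Y
    decoder_heads: int = 10
    decoder_hidden: int = 500
    decoder_dropout: float = 0.5
    vocab_units: int = VOCAB_SIZE
    ff_inner_ratio: int = 4  # feed-forward inner width = ratio * model width
    architecture: str = "transformer"  # or "blstm"

    def __post_init__(self) -> None:
        if self.architecture not in ("transformer", "blstm"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


class Seq2SeqDecoder(Module):
    """Trainable sentence decoder; ``seed`` fixes init and dropout draws."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(seed + 1)
        self.training = False
        c = config

        self.conv = Dense(rng, c.conv_stride * c.n_electrodes, c.conv_filters)
        if c.architecture == "transformer":
            self.encoder = [
                TransformerEncoderLayer(
                    rng, c.encoder_hidden, c.encoder_heads,
                    c.ff_inner_ratio * c.encoder_hidden, c.encoder_dropout,
                )
                for _ in range(c.encoder_layers)
            ]
        else:
            if c.encoder_hidden % 2 != 0:
                raise ValueError("blstm encoder width must be even")
            self.encoder = [BiLSTM(rng, c.conv_filters, c.encoder_hidden // 2)]
        self.ff1 = Dense(rng, c.encoder_hidden, c.mfcc_head_units)

        self.embed = Embedding(rng, c.vocab_units, c.embed_dim)
        if c.architecture == "transformer":
            self.decoder = [
                TransformerDecoderLayer(
                    rng, c.decoder_hidden, c.decoder_heads,
                    c.ff_inner_ratio * c.decoder_hidden, c.decoder_dropout,
                    dim_enc=c.encoder_hidden,
                )
                for _ in range(c.decoder_layers)
            ]
        else:
            self.decoder = [LSTM(rng, c.embed_dim, c.decoder_hidden)]
            self.enc_to_h0 = Dense(rng, c.encoder_hidden, c.decoder_hidden)
            self.enc_to_c0 = Dense(rng, c.encoder_hidden, c.decoder_hidden)
        self.ff2 = Dense(rng, c.decoder_hidden, c.vocab_units)

    # -- stages ------------------------------------------------------------
    def temporal_conv(self, features: Tensor) -> Tensor:
        """(B, L, K) feature batch -> (B, N, C) with N = ceil(L / W)."""
        c = self.config
        b, length, k = features.shape
        if k != c.n_electrodes:
            raise ValueError(f"feature width {k} != configured electrodes {c.n_electrodes}")
        if length < c.conv_stride:
            raise ValueError(f"sequence length {length} shorter than stride {c.conv_stride}")
        n = -(-length // c.conv_stride)
        pad = n * c.conv_stride - length
        if pad:
            from .nn import concat

            x = concat([features, Tensor(np.zeros((b, pad, k)))], axis=1)
        else:
            x = features
        blocks = x.reshape(b, n, c.conv_stride * k)
        out = self.conv(blocks)
        out = dropout(out, c.conv_dropout, self._drop_rng, self.training)
        return out + Tensor(positional_encoding(n, c.conv_filters)[None])

    def encode(self, conv_out: Tensor) -> tuple[Tensor, Tensor]:
        """Encoder stack -> (encoder_output (B,N,100), mfcc_pred (B,N,13))."""
        c = self.config
        if c.architecture == "transformer":
            x = conv_out
            for layer in self.encoder:
                x = layer(x, self._drop_rng, self.training)
            enc = x
            self._enc_final = None
        else:
            seq, h_final = self.encoder[0](conv_out)
            enc = dropout(seq, c.encoder_dropout, self._drop_rng, self.training)
            self._enc_final = h_final
        return enc, self.ff1(enc)

    def decode_logits(self, enc: Tensor, target_in: np.ndarray) -> Tensor:
        """Teacher-forced decoder pass.

        ``target_in`` is the (B, M) right-shifted token matrix beginning with
        the start token; returns logits (B, M, vocab).
        """
        c = self.config
        target_in = np.asarray(target_in, dtype=np.intp)
        b, m = target_in.shape
        x = self.embed(target_in)
        if c.architecture == "transformer":
            x = x + Tensor(positional_encoding(m, c.embed_dim)[None])
            x = dropout(x, c.decoder_dropout, self._drop_rng, self.training)
            mask = causal_mask(m)
            for layer in self.decoder:
                x = layer(x, enc, mask, self._drop_rng, self.training)
        else:
            h0 = self.enc_to_h0(self._enc_final).tanh()
            c0 = self.enc_to_c0(self._enc_final).tanh()
            x, _, _ = self.decoder[0](x, h0, c0)
            x = dropout(x, c.decoder_dropout, self._drop_rng, self.training)
        return self.ff2(x)

    def forward(self, features: Tensor, target_in: np.ndarray) -> tuple[Tensor, Tensor]:
        """Full teacher-forced pass -> (logits (B,M,8), mfcc_pred (B,N,13))."""
        enc, mfcc_pred = self.encode(self.temporal_conv(features))
        return self.decode_logits(enc, target_in), mfcc_pred

    # -- inference ---------------------------------------------------------
    def decode_greedy(self, features: np.ndarray, max_len: int = MAX_TARGET_LEN) -> list[list[int]]:
        """Autoregressive argmax decoding from the start token.

        ``features`` is (B, L, K) or (L, K).  Returns per-item token lists
        excluding the start token; generation stops at the end token (which is
        stripped) or after ``max_len - 1`` generated tokens.  Argmax ties
        break toward the lowest token ID.
        """
        if features.ndim == 2:
            features = features[None]
        was_training = self.training
        self.training = False
        try:
            enc, _ = self.encode(self.temporal_conv(Tensor(features)))
            b = features.shape[0]
            seqs = np.full((b, 1), START_TOKEN, dtype=np.intp)
            done = np.zeros(b, dtype=bool)
            for _ in range(max_len - 1):
                logits = self.decode_logits(enc, seqs)
                nxt = np.argmax(logits.data[:, -1, :], axis=-1)
                nxt[done] = END_TOKEN
                seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
                done |= nxt == END_TOKEN
                if done.all():
                    break
        finally:
            self.training = was_training
        out = []
        for row in seqs:
            toks = [int(t) for t in row[1:]]
            if END_TOKEN in toks:
                toks = toks[: toks.index(END_TOKEN)]
            out.append(toks)
        return out

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        params = self.parameters()
        np.savez(path / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(params)})
        (path / "config.json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Seq2SeqDecoder":
        path = Path(path)
        config = ModelConfig(**json.loads((path / "config.json").read_text()))
        model = cls(config)
        with np.load(path / "weights.npz") as arrays:
            for i, p in enumerate(model.parameters()):
                p.data[...] = arrays[f"p{i}"]
        return model


def build_model(config: ModelConfig, seed: int = 0) -> Seq2SeqDecoder:
    """Construct a decoder; ``architecture`` in the config selects the
    Transformer or the BLSTM variant (identical interface and heads)."""
    return Seq2SeqDecoder(config, seed=seed)
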