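"""SMILES-to-grammar translator: the continuous molecular latent space.

A single-GRU encoder reads the canonical SMILES character-by-character (as
one-hot vectors) and its final cell state, squashed elementwise by tanh,
is the molecule's latent vector.  A single-GRU decoder, initialized with
that latent vector and fed the previous grammar rule at each step (teacher
forcing during training), produces per-step logits over production rules;
decoding applies the stack mask from :mod:`gexmol.grammar`, so the output
is always a grammatically consistent derivation.

The tanh squashing matters downstream: the GAN generators end in tanh, so
real (encoded) and generated latents share the support [−1, 1]^L.

Model/results split follows the usual fit-object idiom:
``SmilesGrammarTranslator(corpus).fit(...)`` returns a
:class:`TranslatorResults` that encodes, decodes, summarizes and saves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from gexmol import grammar as gmr
from gexmol import nn
from gexmol.autodiff import Tensor, concat, grad, no_grad
from gexmol.exceptions import ConfigurationError, DerivationError, EncodingError
from gexmol.synthetic import canonical_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "CharVocabulary",
    "TranslatorConfig",
    "SmilesGrammarTranslator",
    "TranslatorResults",
    "train_translator",
]

PAD_TOKEN = "^"


@dataclass(frozen=True)
class CharVocabulary:
    """Ordered SMILES character set; padding token at index 0."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if self.tokens.count(PAD_TOKEN) != 1 or self.tokens[0] != PAD_TOKEN:
            raise ConfigurationError("padding token must appear exactly once, first")
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    @classmethod
    def from_corpus(cls, corpus: list[str]) -> "CharVocabulary":
        chars = sorted({ch for s in corpus for ch in s})
        if PAD_TOKEN in chars:
            raise ConfigurationError(f"corpus contains the padding character {PAD_TOKEN!r}")
        return cls(tokens=(PAD_TOKEN, *chars))

    def __len__(self):
        return len(self.tokens)

    def encode(self, smiles: str, length: int) -> np.ndarray:
        idx = np.zeros(length, dtype=np.int64)
        if len(smiles) > length:
            raise EncodingError(f"SMILES longer than max_char_len={length}")
        for i, ch in enumerate(smiles):
            j = self.index.get(ch)
            if j is None:
                raise EncodingError(f"character {ch!r} not in vocabulary")
            idx[i] = j
        return idx


@dataclass(frozen=True)
class TranslatorConfig:
    """Translator hyper-parameters.

    Full-scale defaults: 256-d latent space and decoder dropout 0.2.  The
    sequence lengths default to the corpus maxima (rule length at the 99th
    percentile, molecules beyond it are dropped with a logged count).
    """

    latent_dim: int = 256
    dropout: float = 0.2
    max_rule_len: int | None = None
    max_char_len: int | None = None
    learning_rate: float = 5e-3
    batch_size: int = 64
    rule_len_percentile: float = 99.0


class _TranslatorNet(nn.Module):
    """Encoder GRU over characters; decoder GRU over previous-rule one-hots.

    The latent initializes the decoder state and is also re-fed at every
    step (concatenated with the previous rule), so the conditioning signal
    does not fade over long derivations.
    """

    def __init__(self, vocab_size: int, n_rules: int, latent_dim: int, dropout: float, rng):
        self.encoder = nn.GRUCell(vocab_size, latent_dim, rng)
        self.decoder = nn.GRUCell(n_rules + latent_dim, latent_dim, rng)
        self.out = nn.Dense(latent_dim, n_rules, rng)
        self.drop = nn.Dropout(dropout)


class SmilesGrammarTranslator:
    """Model object: a corpus of SMILES plus the translator architecture.

    Unparseable molecules and derivations longer than ``max_rule_len`` are
    skipped with a logged count rather than aborting the build.
    """

    def __init__(
        self,
        corpus: list[str],
        grammar: gmr.GrammarSpec | None = None,
        config: TranslatorConfig | None = None,
    ):
        if not corpus:
            raise ConfigurationError("corpus must be nonempty")
        self.grammar = grammar or gmr.build_grammar()
        config = config or TranslatorConfig()

        parsed: list[tuple[str, np.ndarray, int]] = []
        n_skipped = 0
        for smiles in corpus:
            try:
                smi = canonical_smiles(smiles)
                seq = gmr.smiles_to_rules(smi, self.grammar, max_len=10_000)
                length = gmr.derivation_length(seq, self.grammar)
                parsed.append((smi, seq.indices[:length], length))
            except Exception:
                n_skipped += 1
        if not parsed:
            raise ConfigurationError("no corpus molecule parses under the grammar")
        if n_skipped:
            logger.warning("skipped %d unparseable corpus molecules", n_skipped)

        lengths = np.array([p[2] for p in parsed])
        if config.max_rule_len is None:
            T = int(np.ceil(np.percentile(lengths, config.rule_len_percentile)))
            config = replace(config, max_rule_len=T)
        kept = [p for p in parsed if p[2] <= config.max_rule_len]
        n_dropped = len(parsed) - len(kept)
        if n_dropped:
            logger.warning(
                "dropped %d molecules with derivations longer than T=%d",
                n_dropped,
                config.max_rule_len,
            )
        if config.max_char_len is None:
            config = replace(config, max_char_len=max(len(p[0]) for p in kept))

        self.config = config
        self.corpus = [p[0] for p in kept]
        self.n_skipped = n_skipped + n_dropped
        self.vocab = CharVocabulary.from_corpus(self.corpus)

        T = config.max_rule_len
        pad = self.grammar.padding_rule_index
        n = len(kept)
        self._rule_targets = np.full((n, T), pad, dtype=np.int64)
        self._rule_mask = np.zeros((n, T), dtype=np.float64)
        for i, (_, idx, length) in enumerate(kept):
            self._rule_targets[i, :length] = idx
            self._rule_mask[i, :length] = 1.0
        self._char_idx = np.stack(
            [self.vocab.encode(p[0], config.max_char_len) for p in kept]
        )

    # -- fitting ------------------------------------------------------------
    def fit(self, epochs: int = 50, seed: int = 0, verbose: bool = False) -> "TranslatorResults":
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        init_rng, shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(3))
        net = _TranslatorNet(
            len(self.vocab), self.grammar.n_rules, cfg.latent_dim, cfg.dropout, init_rng
        )
        params = net.parameters()
        opt = nn.RMSprop(params, lr=cfg.learning_rate)

        n = len(self.corpus)
        V, R = len(self.vocab), self.grammar.n_rules
        char_onehot = np.eye(V)[self._char_idx]  # (n, Tc, V)
        char_mask = (self._char_idx != 0).astype(np.float64)
        target_onehot = np.eye(R)[self._rule_targets]  # (n, T, R)
        # teacher-forcing inputs: zero vector at t=0, then previous target rule
        dec_inputs = np.zeros_like(target_onehot)
        dec_inputs[:, 1:, :] = target_onehot[:, :-1, :]

        loss_history: list[float] = []
        acc_history: list[float] = []
        for epoch in range(epochs):
            order = shuffle_rng.permutation(n)
            tot_loss = tot_correct = tot_count = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss, correct, count = self._batch_loss(
                    net,
                    char_onehot[batch],
                    char_mask[batch],
                    dec_inputs[batch],
                    target_onehot[batch],
                    self._rule_mask[batch],
                    training=True,
                    rng=drop_rng,
                )
                grads = grad(loss, params)
                opt.step(grads)
                tot_loss += float(loss.data) * count
                tot_correct += correct
                tot_count += count
            loss_history.append(tot_loss / tot_count)
            acc_history.append(tot_correct / tot_count)
            if verbose:
                logger.info(
                    "epoch %d: loss %.4f, token accuracy %.3f",
                    epoch,
                    loss_history[-1],
                    acc_history[-1],
                )
        return TranslatorResults(
            model=self,
            net=net,
            loss_history=np.array(loss_history),
            accuracy_history=np.array(acc_history),
            seed=seed,
        )

    def _batch_loss(self, net, chars, cmask, dec_in, targets, tmask, training, rng):
        latent = _encode_forward(net, chars, cmask)
        h = latent
        step_logits = []
        for t in range(dec_in.shape[1]):
            x_t = concat([Tensor(dec_in[:, t, :]), latent], axis=1)
            h = net.decoder.step(x_t, h)
            hd = net.drop(h, training=training, rng=rng)
            step_logits.append(net.out(hd))
        # masked softmax cross-entropy over rule targets
        loss = None
        correct = 0.0
        for t, logits in enumerate(step_logits):
            shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
            logz = shift.exp().sum(axis=1, keepdims=True).log()
            logp = shift - logz
            tgt = Tensor(targets[:, t, :])
            m = Tensor(tmask[:, t : t + 1])
            nll = -1.0 * ((logp * tgt).sum(axis=1, keepdims=True) * m).sum()
            loss = nll if loss is None else loss + nll
            pred = logits.data.argmax(axis=1)
            truth = targets[:, t, :].argmax(axis=1)
            correct += float(((pred == truth) * tmask[:, t]).sum())
        count = float(tmask.sum())
        return loss * (1.0 / count), correct, count


def _encode_forward(net: _TranslatorNet, chars: np.ndarray, cmask: np.ndarray) -> Tensor:
    """GRU over one-hot characters; padding positions leave the state unchanged."""
    B, Tc, _ = chars.shape
    h = Tensor(np.zeros((B, net.encoder.nh)))
    for t in range(Tc):
        m = Tensor(cmask[:, t : t + 1])
        h_new = net.encoder.step(Tensor(chars[:, t, :]), h)
        h = m * h_new + (1.0 - m) * h
    return h.tanh()


# ---------------------------------------------------------------------------
# results


@dataclass
class TranslatorResults:
    """Fitted translator: latent encodings, grammar-masked decoding, history."""

    model: SmilesGrammarTranslator
    net: _TranslatorNet
    loss_history: np.ndarray
    accuracy_history: np.ndarray
    seed: int = 0

    @property
    def config(self) -> TranslatorConfig:
        return self.model.config

    @property
    def grammar(self) -> gmr.GrammarSpec:
        return self.model.grammar

    @property
    def vocab(self) -> CharVocabulary:
        return self.model.vocab

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    @property
    def token_accuracy(self) -> float:
        return float(self.accuracy_history[-1])

    # -- encoding -----------------------------------------------------------
    def encode(self, smiles: str) -> np.ndarray:
        return self.encode_batch([smiles])[0]

    def encode_batch(self, smiles_list: list[str]) -> np.ndarray:
        cfg = self.config
        idx = np.stack([self.vocab.encode(s, cfg.max_char_len) for s in smiles_list])
        chars = np.eye(len(self.vocab))[idx]
        cmask = (idx != 0).astype(np.float64)
        with no_grad():
            latent = _encode_forward(self.net, chars, cmask)
        return latent.data

    # -- decoding -----------------------------------------------------------
    def decode_sequences(
        self, latents: np.ndarray, mode: str = "argmax", seed: int | None = None
    ) -> list[gmr.RuleSequence]:
        """Batched stack-masked decoding of latent vectors to rule sequences."""
        if mode not in ("argmax", "sample"):
            raise ConfigurationError(f"unknown decode mode {mode!r}")
        latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
        if latents.shape[1] != self.latent_dim:
            raise ConfigurationError(
                f"latent dimension {latents.shape[1]} != configured {self.latent_dim}"
            )
        grammar = self.grammar
        cfg = self.config
        B = latents.shape[0]
        T, R = cfg.max_rule_len, grammar.n_rules
        rng = np.random.default_rng(seed)
        masks = gmr.lhs_masks(grammar)

        w = self.net.state_dict()
        h = latents.copy()
        prev = np.zeros((B, R))
        stacks = [[grammar.start_symbol] for _ in range(B)]
        out = np.full((B, T), grammar.padding_rule_index, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        for t in range(T):
            if done.all():
                break
            h = _gru_step_np(w, "decoder", np.concatenate([prev, latents], axis=1), h)
            logits = h @ w["out.weight"] + w["out.bias"]
            prev = np.zeros((B, R))
            for b in range(B):
                if done[b]:
                    continue
                stack = stacks[b]
                while stack and grammar.is_terminal(stack[-1]):
                    stack.pop()
                if not stack:
                    done[b] = True
                    continue
                row = np.where(masks[stack[-1]], logits[b], -np.inf)
                if mode == "argmax":
                    choice = int(np.argmax(row))
                else:
                    p = np.exp(row - row.max())
                    p /= p.sum()
                    choice = int(rng.choice(R, p=p))
                out[b, t] = choice
                stack.pop()
                stack.extend(reversed(grammar.rules[choice].rhs))
                prev[b, choice] = 1.0
        sequences = []
        for b in range(B):
            stack = [s for s in stacks[b] if not grammar.is_terminal(s)]
            sequences.append(
                gmr.RuleSequence(out[b], grammar.n_rules, truncated=bool(stack))
            )
        return sequences

    def decode(self, latent: np.ndarray, mode: str = "argmax", seed: int | None = None) -> str:
        seq = self.decode_sequences(latent, mode=mode, seed=seed)[0]
        if seq.truncated:
            raise DerivationError("decoding truncated at max rule length")
        return gmr.rules_to_smiles(seq, self.grammar)

    def decode_batch(
        self, latents: np.ndarray, mode: str = "argmax", seed: int | None = None
    ) -> list[str | None]:
        """Decode many latents; ``None`` marks sequences truncated at T."""
        results = []
        for seq in self.decode_sequences(latents, mode=mode, seed=seed):
            if seq.truncated:
                results.append(None)
            else:
                try:
                    results.append(gmr.rules_to_smiles(seq, self.grammar))
                except DerivationError:
                    results.append(None)
        return results

    # -- reporting / persistence ---------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "SMILES-to-grammar translator",
            "=" * 34,
            f"corpus molecules      {len(self.model.corpus)}",
            f"skipped molecules     {self.model.n_skipped}",
            f"latent dimension      {cfg.latent_dim}",
            f"max rule length (T)   {cfg.max_rule_len}",
            f"vocabulary size       {len(self.vocab)}",
            f"grammar rules (R)     {self.grammar.n_rules}",
            f"epochs trained        {len(self.loss_history)}",
            f"final loss            {self.loss_history[-1]:.4f}",
            f"token accuracy        {self.token_accuracy:.3f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        cfg = self.config
        config = {
            "kind": "gexmol-translator",
            "schema": 1,
            "latent_dim": cfg.latent_dim,
            "dropout": cfg.dropout,
            "max_rule_len": cfg.max_rule_len,
            "max_char_len": cfg.max_char_len,
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "vocab": list(self.vocab.tokens),
            "corpus": self.model.corpus,
            "seed": self.seed,
        }
        state = self.net.state_dict()
        state["history/loss"] = self.loss_history
        state["history/accuracy"] = self.accuracy_history
        nn.save_archive(path, config, state)

    @classmethod
    def load(cls, path) -> "TranslatorResults":
        config, state = nn.load_archive(path)
        if config.get("kind") != "gexmol-translator":
            raise ConfigurationError("not a translator archive")
        cfg = TranslatorConfig(
            latent_dim=config["latent_dim"],
            dropout=config["dropout"],
            max_rule_len=config["max_rule_len"],
            max_char_len=config["max_char_len"],
            learning_rate=config["learning_rate"],
            batch_size=config["batch_size"],
        )
        model = SmilesGrammarTranslator(config["corpus"], config=cfg)
        rng = np.random.default_rng(0)
        net = _TranslatorNet(
            len(model.vocab), model.grammar.n_rules, cfg.latent_dim, cfg.dropout, rng
        )
        loss = state.pop("history/loss")
        acc = state.pop("history/accuracy")
        net.load_state_dict(state)
        return cls(
            model=model,
            net=net,
            loss_history=np.asarray(loss),
            accuracy_history=np.asarray(acc),
            seed=config.get("seed", 0),
        )


def _gru_step_np(w: dict[str, np.ndarray], prefix: str, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Plain-numpy GRU step (inference path, no graph)."""

    def sig(a):
        return 1.0 / (1.0 + np.exp(-a))

    z = sig(x @ w[f"{prefix}.w_z"] + h @ w[f"{prefix}.u_z"] + w[f"{prefix}.b_z"])
    r = sig(x @ w[f"{prefix}.w_r"] + h @ w[f"{prefix}.u_r"] + w[f"{prefix}.b_r"])
    h_cand = np.tanh(x @ w[f"{prefix}.w_h"] + (r * h) @ w[f"{prefix}.u_h"] + w[f"{prefix}.b_h"])
    return (1.0 - z) * h + z * h_cand


def train_translator(
    corpus: list[str],
    grammar: gmr.GrammarSpec | None = None,
    config: TranslatorConfig | None = None,
    epochs: int = 50,
    seed: int = 0,
) -> TranslatorResults:
    """Functional wrapper: build the model and fit it in one call."""
    return SmilesGrammarTranslator(corpus, grammar=grammar, config=config).fit(
        epochs=epochs, seed=seed
    )
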