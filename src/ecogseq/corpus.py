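"""Eight-sentence Japanese phrase corpus, token mapping, and trial schedules.

Sentences are built from three slots with two phrase options each
(2 x 2 x 2 = 8 sentences).  Each of the six phrases carries an integer token
ID 0-5; IDs 6 and 7 are reserved for the start- and end-of-sentence markers.
A decoded sentence is the token sequence ``[6, t1, t2, t3, 7]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

START_TOKEN = 6
END_TOKEN = 7
VOCAB_SIZE = 8
N_SCORED_TOKENS = 3  # phrases per sentence; start/end are never scored


@dataclass(frozen=True)
class PhraseOption:
    romaji: str
    gloss: str
    token_id: int


@dataclass(frozen=True)
class PhraseInventory:
    """Three ordered slots, two phrase options per slot."""

    slots: tuple[tuple[PhraseOption, PhraseOption], ...]

    def __post_init__(self) -> None:
        if len(self.slots) != 3:
            raise ValueError(f"inventory must have exactly 3 slots, got {len(self.slots)}")
        for i, slot in enumerate(self.slots):
            if len(slot) != 2:
                raise ValueError(f"slot {i} must have exactly 2 options, got {len(slot)}")
        ids = sorted(opt.token_id for slot in self.slots for opt in slot)
        if ids != [0, 1, 2, 3, 4, 5]:
            raise ValueError(f"phrase token ids must be exactly 0..5, got {ids}")

    def lookup(self, romaji: str) -> PhraseOption:
        for slot in self.slots:
            for opt in slot:
                if opt.romaji == romaji:
                    return opt
        raise KeyError(f"unknown phrase: {romaji!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "slots": [
                    {"options": [{"romaji": o.romaji, "gloss": o.gloss, "token_id": o.token_id} for o in slot]}
                    for slot in self.slots
                ],
                "start_token": START_TOKEN,
                "end_token": END_TOKEN,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhraseInventory":
        obj = json.loads(text)
        slots = tuple(
            tuple(PhraseOption(o["romaji"], o["gloss"], int(o["token_id"])) for o in slot["options"])
            for slot in obj["slots"]
        )
        return cls(slots=slots)


#: The study corpus: slot 1 subject, slot 2 destination, slot 3 verb.
DEFAULT_INVENTORY = PhraseInventory(
    slots=(
        (PhraseOption("watashiwa", "I", 0), PhraseOption("kimito", "with you", 1)),
        (PhraseOption("gakko:e", "to school", 2), PhraseOption("shokubani", "to the office", 3)),
        (PhraseOption("itta", "went", 4), PhraseOption("mukau", "head", 5)),
    )
)


@dataclass(frozen=True)
class SentenceSpec:
    choices: tuple[int, int, int]  # option index (0 or 1) per slot
    romaji: str
    token_sequence: tuple[int, ...] = field(default=())  # [6, t1, t2, t3, 7]

    @property
    def scored_tokens(self) -> tuple[int, ...]:
        return self.token_sequence[1:-1]


def build_sentences(inventory: PhraseInventory = DEFAULT_INVENTORY) -> list[SentenceSpec]:
    """Cartesian product of the slot options, slot-1 major order.

    Returns the 8 sentence patterns; sentence index i has choices equal to the
    binary digits of i (most significant digit = slot 1).
    """
    sentences = []
    for choices in product((0, 1), repeat=3):
        opts = [inventory.slots[s][c] for s, c in enumerate(choices)]
        tokens = (START_TOKEN, *[o.token_id for o in opts], END_TOKEN)
        sentences.append(
            SentenceSpec(
                choices=tuple(choices),
                romaji=" ".join(o.romaji for o in opts),
                token_sequence=tokens,
            )
        )
    return sentences


def tokenize(romaji: str, inventory: PhraseInventory = DEFAULT_INVENTORY) -> list[int]:
    """Map a romaji phrase triple to ``[6, t1, t2, t3, 7]``."""
    phrases = romaji.split()
    if len(phrases) != 3:
        raise ValueError(f"expected 3 phrases, got {len(phrases)}: {romaji!r}")
    return [START_TOKEN] + [inventory.lookup(p).token_id for p in phrases] + [END_TOKEN]


def detokenize(tokens: list[int] | tuple[int, ...], inventory: PhraseInventory = DEFAULT_INVENTORY) -> str:
    """Inverse of :func:`tokenize`; accepts sequences with or without markers."""
    by_id = {opt.token_id: opt.romaji for slot in inventory.slots for opt in slot}
    inner = [t for t in tokens if t not in (START_TOKEN, END_TOKEN)]
    try:
        return " ".join(by_id[t] for t in inner)
    except KeyError as e:
        raise KeyError(f"token id {e.args[0]} is not a phrase token") from None


@dataclass(frozen=True)
class TrialSchedule:
    """Balanced, seeded-shuffled ordering of sentence indices over trials."""

    sentence_indices: tuple[int, ...]
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.sentence_indices)

    def to_csv(self) -> str:
        df = pd.DataFrame(
            {"trial_index": range(self.n_trials), "sentence_index": self.sentence_indices}
        )
        return f"# seed={self.seed}\n" + df.to_csv(index=False)


def make_schedule(n_trials: int, seed: int) -> TrialSchedule:
    """Balanced multiset of the 8 sentences, permuted by a seeded RNG.

    Each sentence appears exactly ``n_trials / 8`` times (80 trials -> 10
    appearances); ``n_trials`` must be divisible by 8.
    """
    if n_trials % 8 != 0:
        raise ValueError(f"n_trials must be divisible by 8, got {n_trials}")
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(8), n_trials // 8)
    rng.shuffle(order)
    return TrialSchedule(sentence_indices=tuple(int(i) for i in order), seed=seed)
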