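"""Seeded generators for terminologies, idiom lexica and interaction logs.

The simulator emulates the statistical regime of a hospital
phrase-prediction log: label popularity follows a Zipf (power-law)
distribution, users select the same label repeatedly (so user-label
seniority accumulates), early queries lean on jargon acronyms or short
text prefixes, and — when adaptation is enabled — agents progressively
adopt queries that Pareto-dominate their current one on the two
objectives (query length, label rank).

Terminologies are built from a bundled French-like clinical word pool.
A fraction of labels come in *families*: a base label ("hypertension
artérielle") plus qualified variants ("… sévère", "… stade 2") that all
share the base's acronym as a searchable synonym.  The shared acronym is
the family's jargon idiom: it retrieves every member, so it is feasible
everywhere but optimal only for the base label — the structural reason
idiom usage can decline as agents adapt.  Most labels additionally carry
a distinctive private acronym synonym that retrieves them at rank 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._wordpool import QUALIFIERS, WORDS
from .idiom_analysis import IdiomLexicon
from .terminology_completion import (
    Alphabet,
    CompletionEngine,
    DEFAULT_ALPHABET,
    Label,
    Terminology,
    normalize,
)

__all__ = [
    "SimulationConfig",
    "InteractionRecord",
    "AgentState",
    "acronym_of",
    "generate_terminology",
    "idiom_lexicon_for",
    "sample_label_weights",
    "evaluate_objectives",
    "simulate_log",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the interaction-log simulator.

    ``epsilon0`` and ``decay`` parameterise the exploration schedule
    ε(s) = ε₀·decay^(s−1): the probability that an agent at user-label
    seniority s reconsiders its query.  The defaults make naive initial
    queries fade over roughly the first five selections.
    """

    n_users: int = 200
    n_labels: int = 300
    n_events: int = 50_000
    zipf_s: float = 1.0
    epsilon0: float = 0.8
    decay: float = 0.85
    idiom_start_prob: float = 0.8
    adaptation_enabled: bool = True
    scalarized: bool = False
    scalar_weight: float = 0.5
    seed: int = 0
    J: int = 30

    def __post_init__(self) -> None:
        if min(self.n_users, self.n_labels, self.n_events) < 1:
            raise ValueError("n_users, n_labels and n_events must be >= 1")
        if self.zipf_s <= 0:
            raise ValueError("zipf_s must be positive")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must be in (0, 1]")
        for name in ("epsilon0", "idiom_start_prob", "scalar_weight"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class InteractionRecord:
    """One tool use: who queried what and which label they selected."""

    user: str
    query: str
    label_id: int
    tick: int


@dataclass
class AgentState:
    """Per (user, label) memory of the best query found so far."""

    best_known_query: str
    best_objectives: tuple[int, int]  # (query length k, label rank j)
    seniority: int = 1


def acronym_of(text: str, alphabet: Alphabet = DEFAULT_ALPHABET) -> str:
    """Initials of the normalized words of ``text`` ("alpha beta gamma" → "abg")."""
    return "".join(w[0] for w in normalize(text, alphabet).split())


def generate_terminology(
    n_labels: int,
    seed: int,
    family_fraction: float = 0.5,
    max_family_size: int = 4,
    private_acronym_prob: float = 0.85,
) -> Terminology:
    """Build a synthetic clinical terminology of ``n_labels`` labels.

    ``family_fraction`` is the probability that each new block of labels
    is a family (base + qualified variants sharing the base acronym as a
    synonym) rather than a standalone label.  With probability
    ``private_acronym_prob`` a label also gets a distinctive acronym
    synonym of its own full text.  Deterministic given ``seed``.
    """
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    rng = np.random.default_rng(seed)
    words = tuple(dict.fromkeys(WORDS))
    used_texts: set[str] = set()
    used_syns: set[str] = set()

    def unique_acronym(text: str, min_len: int = 2) -> Optional[str]:
        base = acronym_of(text)
        if len(base) < min_len:
            return None
        candidate = base
        last_word = normalize(text).split()[-1]
        for extra in range(1, len(last_word)):
            if candidate not in used_syns and candidate not in used_texts:
                used_syns.add(candidate)
                return candidate
            candidate = base + last_word[1 : 1 + extra]
        return None

    def variant_private(shared: str, qualifier: str) -> Optional[str]:
        # Distinctive synonym no longer than the shared family acronym, so
        # it can Pareto-dominate the idiom on (length, rank).
        letters = "".join(normalize(qualifier).split())
        for ch in letters:
            candidate = shared[:-1] + ch
            if (
                candidate != shared
                and candidate not in used_syns
                and candidate not in used_texts
            ):
                used_syns.add(candidate)
                return candidate
        return None

    labels: list[Label] = []
    next_id = 1
    while len(labels) < n_labels:
        n_words = int(rng.integers(2, 4))  # base texts of 2-3 words
        idx = rng.choice(len(words), size=n_words, replace=False)
        base_text = " ".join(words[i] for i in idx)
        if normalize(base_text) in used_texts:
            continue
        remaining = n_labels - len(labels)
        make_family = rng.random() < family_fraction and remaining >= 2
        if make_family:
            fam_size = int(rng.integers(2, max_family_size + 1))
            fam_size = min(fam_size, remaining)
            shared = unique_acronym(base_text)
            qual_idx = rng.choice(len(QUALIFIERS), size=fam_size - 1, replace=False)
            texts = [base_text] + [
                f"{base_text} {QUALIFIERS[i]}" for i in qual_idx
            ]
            texts = [t for t in texts if normalize(t) not in used_texts]
            for i, text in enumerate(texts):
                syns = [] if shared is None else [shared]
                if i > 0 and rng.random() < private_acronym_prob:
                    # variants get a distinctive same-length synonym; the
                    # base label is already ranked first under the idiom
                    if shared is not None:
                        priv = variant_private(shared, text[len(base_text) + 1 :])
                    else:
                        priv = unique_acronym(text, min_len=3)
                    if priv is not None:
                        syns.append(priv)
                used_texts.add(normalize(text))
                labels.append(Label(next_id, text, tuple(syns)))
                next_id += 1
        else:
            syns = []
            if rng.random() < private_acronym_prob:
                priv = unique_acronym(base_text)
                if priv is not None:
                    syns.append(priv)
            used_texts.add(normalize(base_text))
            labels.append(Label(next_id, base_text, tuple(syns)))
            next_id += 1
    return Terminology(tuple(labels[:n_labels]))


def idiom_lexicon_for(terminology: Terminology) -> IdiomLexicon:
    """The jargon lexicon paired with a generated terminology.

    The jargon an entire community shares maps to synonyms attached to
    more than one label (family acronyms such as "hta"); private
    single-label synonyms model user-discovered shortcuts and are not
    jargon.  Shared synonyms therefore form the lexicon.
    """
    counts: dict[str, int] = {}
    for lab in terminology:
        for syn in lab.synonyms:
            s = normalize(syn)
            if s:
                counts[s] = counts.get(s, 0) + 1
    shared = [s for s, c in counts.items() if c > 1]
    return IdiomLexicon.from_strings(shared)


def sample_label_weights(n_labels: int, s: float) -> np.ndarray:
    """Zipf selection probabilities: weight of rank-r label ∝ r^(−s)."""
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    if s <= 0:
        raise ValueError("zipf exponent s must be positive")
    ranks = np.arange(1, n_labels + 1, dtype=float)
    w = ranks ** (-s)
    return w / w.sum()


def evaluate_objectives(
    query: str, label_id: int, engine: CompletionEngine
) -> Optional[tuple[int, int]]:
    """(query length, label rank) for a query, or ``None`` when infeasible."""
    q = normalize(query, engine.alphabet)
    if not q:
        return None
    j = engine.rank_of(label_id, q)
    return None if j is None else (len(q), j)


def _candidate_pool(label: Label, engine: CompletionEngine) -> list[str]:
    """Deterministic pool of plausible alternative queries for one label.

    Canonical-text prefixes, the label's own synonyms, its full acronym,
    and first-word + second-word-prefix combinations.
    """
    nt = normalize(label.canonical_text, engine.alphabet)
    pool: list[str] = []
    for ell in range(2, min(len(nt), 12) + 1):
        pool.append(nt[:ell].strip())
    for syn in label.synonyms:
        s = normalize(syn, engine.alphabet)
        if s:
            pool.append(s)
    acr = acronym_of(nt)
    if len(acr) >= 2:
        pool.append(acr)
    tokens = nt.split()
    if len(tokens) >= 2:
        for m in range(1, min(3, len(tokens[1])) + 1):
            pool.append(f"{tokens[0]} {tokens[1][:m]}")
    return list(dict.fromkeys(q for q in pool if q))


def simulate_log(
    config: SimulationConfig,
    terminology: Terminology,
    lexicon: Optional[IdiomLexicon] = None,
    engine: Optional[CompletionEngine] = None,
) -> list[InteractionRecord]:
    """Simulate a seeded interaction log.

    Per event a label is drawn by Zipf weights and a user uniformly.  A
    (user, label) pair's first query is the label's jargon idiom (with
    probability ``idiom_start_prob``, when one exists) or a random short
    prefix of the label text, grown until the label is retrievable within
    the suggestion cap.  On later selections the agent, with probability
    ε(seniority), samples a few candidate queries and adopts one that
    weakly Pareto-dominates its current best on (length, rank); otherwise
    it reuses its best known query.  Ticks increase strictly; the run is
    fully reproducible from ``config.seed``.
    """
    for lab in terminology:
        if not normalize(lab.canonical_text):
            raise ValueError(f"label {lab.label_id} has empty normalized text")
    if engine is None:
        engine = CompletionEngine(terminology, J=config.J)
    if lexicon is None:
        lexicon = idiom_lexicon_for(terminology)
    rng = np.random.default_rng(config.seed)

    labels = list(terminology)
    n = len(labels)
    weights = sample_label_weights(n, config.zipf_s)
    perm = rng.permutation(n)  # popularity rank -> label index
    w = np.empty(n)
    w[perm] = weights
    label_draws = rng.choice(n, size=config.n_events, p=w)
    user_draws = rng.integers(0, config.n_users, size=config.n_events)

    idiom_by_label: dict[int, str] = {}
    for lab in labels:
        for syn in lab.synonyms:
            s = normalize(syn)
            if s in lexicon:
                idiom_by_label[lab.label_id] = s
                break
    norm_texts = {lab.label_id: normalize(lab.canonical_text) for lab in labels}
    pools: dict[int, list[str]] = {}
    states: dict[tuple[int, int], AgentState] = {}
    records: list[InteractionRecord] = []

    def initial_query(lab: Label) -> str:
        idiom = idiom_by_label.get(lab.label_id)
        if idiom is not None and rng.random() < config.idiom_start_prob:
            return idiom
        nt = norm_texts[lab.label_id]
        hi = min(8, len(nt))
        ell = int(rng.integers(2, hi + 1)) if hi > 2 else len(nt)
        while True:
            q = nt[:ell].strip()
            if q and engine.rank_of(lab.label_id, q) is not None:
                return q
            ell += 1
            if ell > len(nt):
                return nt  # full text is an exact match, always feasible

    def try_adapt(lab: Label, st: AgentState) -> None:
        pool = pools.get(lab.label_id)
        if pool is None:
            pool = pools[lab.label_id] = _candidate_pool(lab, engine)
        n_samp = min(3, len(pool))
        if n_samp == 0:
            return
        picks = rng.choice(len(pool), size=n_samp, replace=False)
        best_k, best_j = st.best_objectives
        chosen: Optional[tuple[int, int, str]] = None
        for i in sorted(int(p) for p in picks):
            q = pool[i]
            obj = evaluate_objectives(q, lab.label_id, engine)
            if obj is None:
                continue
            k, j = obj
            if config.scalarized:
                cur = config.scalar_weight * best_k + (1 - config.scalar_weight) * best_j
                cand = config.scalar_weight * k + (1 - config.scalar_weight) * j
                better = cand < cur
            else:
                better = k <= best_k and j <= best_j
            if better and (chosen is None or (j, k, q) < chosen):
                chosen = (j, k, q)
        if chosen is not None:
            st.best_objectives = (chosen[1], chosen[0])
            st.best_known_query = chosen[2]

    for tick in range(config.n_events):
        li = int(label_draws[tick])
        lab = labels[li]
        u = int(user_draws[tick])
        key = (u, li)
        st = states.get(key)
        if st is None:
            q = initial_query(lab)
            obj = evaluate_objectives(q, lab.label_id, engine)
            assert obj is not None
            st = AgentState(best_known_query=q, best_objectives=obj, seniority=1)
            states[key] = st
        else:
            st.seniority += 1
            eps = config.epsilon0 * config.decay ** (st.seniority - 1)
            if config.adaptation_enabled and rng.random() < eps:
                try_adapt(lab, st)
        records.append(
            InteractionRecord(
                user=f"u{u:04d}",
                query=st.best_known_query,
                label_id=lab.label_id,
                tick=tick,
            )
        )
    return records
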