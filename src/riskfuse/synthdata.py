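"""Synthetic matched case-control EHR corpora.

Real cohorts of this design are access-restricted, so every pipeline stage is
exercised on generated data that reproduces the design's load-bearing
structure: 1:k case-control match groups sharing an exact risk percentile and
facility, tier-dependent note volumes (negative-binomial, moment-matched to
the observed per-tier means/SDs — the observed SDs far exceed the means,
ruling out Poisson), Zipf-distributed background vocabularies whose size
varies by tier (so document-frequency filtering is consequential), and
case-associated signal plantable either in lexicon terms ("semantic" signal)
or in idiosyncratic tokens no lexicon contains ("count" signal).

Signal is planted by multiplying the *frequency* of signal tokens in case
notes by ``effect_size``, never by introducing case-exclusive tokens, so
classification stays non-trivial at moderate effect sizes. Under
``signal_mode="none"`` case and control token distributions are identical in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import assign_tier, validate_cohort
from .semantic_features import DEFAULT_NEGATORS, Lexicon, LexiconCategory

#: Per-(tier, status) mean/SD of notes per patient in the analysis window.
DEFAULT_NOTE_COUNT_PARAMS = {
    ("high", "case"): (37.9, 53.9),
    ("high", "control"): (40.0, 82.3),
    ("moderate", "case"): (15.0, 32.7),
    ("moderate", "control"): (12.2, 40.9),
    ("low", "case"): (9.1, 18.5),
    ("low", "control"): (7.0, 19.0),
}

#: Background vocabulary sizes per tier (moderate largest, low smallest,
#: mirroring the ordering of per-tier corpus vocabularies at study scale).
DEFAULT_VOCAB_SIZE = {"high": 2500, "moderate": 2750, "low": 1100}

#: Cohort tier composition (case proportions observed in matched cohorts of
#: this design: roughly 14% high, 50% moderate, 36% low).
DEFAULT_TIER_MIX = {"high": 0.14, "moderate": 0.50, "low": 0.36}

SEMANTIC_SIGNAL_PREFIX = "sx"
COUNT_SIGNAL_PREFIX = "qz"
CALM_PREFIX = "cx"


@dataclass
class GeneratorSpec:
    """Full parameterization of a synthetic corpus."""

    n_cases: int
    controls_per_case: int = 5
    tier_mix: dict = field(default_factory=lambda: dict(DEFAULT_TIER_MIX))
    note_count_params: dict = field(default_factory=lambda: dict(DEFAULT_NOTE_COUNT_PARAMS))
    vocab_size: dict = field(default_factory=lambda: dict(DEFAULT_VOCAB_SIZE))
    tokens_per_note: tuple = (200.0, 150.0)
    zipf_exponent: float = 1.1
    signal_mode: str = "none"  # none | semantic | count | mixed
    effect_size: float = 3.0
    n_signal_terms: int = 40
    signal_rate: float = 0.005
    negator_rate: float = 0.01
    decoy_fraction: float = 0.25
    n_facilities: int = 8
    index_span_days: int = 730
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.tier_mix.values()) - 1.0) > 1e-9:
            raise ValueError("tier_mix proportions must sum to 1")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")
        if self.signal_mode not in ("none", "semantic", "count", "mixed"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")


@dataclass
class SyntheticCorpus:
    cohort: pd.DataFrame
    notes: pd.DataFrame
    truth: dict
    lexicon: Lexicon


def signal_lexicon(spec: GeneratorSpec) -> Lexicon:
    """The synthetic lexicon the generator plants semantic signal into.

    Two categories: ``distress`` holds the semantic-signal terms (elevated in
    case notes under semantic/mixed modes) and ``calm`` holds decoy terms
    present at base rate in both arms. Both emit a 3-token negation variant.
    """
    sem = [f"{SEMANTIC_SIGNAL_PREFIX}{i:03d}" for i in range(spec.n_signal_terms)]
    calm = [f"{CALM_PREFIX}{i:03d}" for i in range(spec.n_signal_terms)]
    return Lexicon(
        name="synthlex",
        categories=[
            LexiconCategory("distress", frozenset(sem), "negative", (3,)),
            LexiconCategory("calm", frozenset(calm), "positive", (3,)),
        ],
    )


def generate_cohort(spec: GeneratorSpec) -> pd.DataFrame:
    """Matched cohort: each case plus ``controls_per_case`` exact matches.

    Percentiles follow the tier: high → 1, moderate → uniform 2–24, low →
    uniform 25–100. All members of a match group share percentile, facility
    and index date; index dates spread over ``index_span_days``. Two
    structural covariates (age, female) are drawn identically in both arms.
    """
    rng = np.random.default_rng(spec.seed)
    tiers = list(spec.tier_mix)
    probs = np.array([spec.tier_mix[t] for t in tiers], float)
    base = pd.Timestamp("2017-01-01")
    rows = []
    pid = 0
    for gi in range(spec.n_cases):
        tier = rng.choice(tiers, p=probs)
        if tier == "high":
            perc = 1
        elif tier == "moderate":
            perc = int(rng.integers(2, 25))
        else:
            perc = int(rng.integers(25, 101))
        index_date = base + pd.Timedelta(days=int(rng.integers(0, spec.index_span_days)))
        facility = f"fac{int(rng.integers(spec.n_facilities)):02d}"
        mg = f"mg{gi:06d}"
        for status in ["case"] + ["control"] * spec.controls_per_case:
            rows.append({
                "patient_id": f"p{pid:06d}",
                "status": status,
                "index_date": index_date,
                "percentile": perc,
                "tier": assign_tier(perc),
                "match_group": mg,
                "facility": facility,
                "age": float(np.clip(rng.normal(60, 16), 18, 101)),
                "female": int(rng.random() < 0.06),
            })
            pid += 1
    return validate_cohort(pd.DataFrame(rows))


def _nbinom_draws(rng, mean, sd, size):
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)
    return rng.poisson(mean, size=size)


def generate_notes(cohort: pd.DataFrame, spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Generate note text and dates for every cohort patient.

    Per patient, the in-window note count is negative-binomial (moment-matched
    to the tier/status mean and SD, truncated at 1) with dates uniform 5–30
    days before the index date; ``decoy_fraction`` extra notes land at 0–4 or
    31–60 days out to exercise the window filter. Each token position is a
    negation cue, a semantic-signal term, a count-signal term, a decoy lexicon
    term, or a Zipf background word; case notes multiply the active signal
    set's rate by ``effect_size``. Returns the notes and the planted-truth
    record.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sem_terms = np.array([f"{SEMANTIC_SIGNAL_PREFIX}{i:03d}" for i in range(spec.n_signal_terms)], object)
    cnt_terms = np.array([f"{COUNT_SIGNAL_PREFIX}{i:03d}" for i in range(spec.n_signal_terms)], object)
    calm_terms = np.array([f"{CALM_PREFIX}{i:03d}" for i in range(spec.n_signal_terms)], object)
    negators = np.array(sorted(DEFAULT_NEGATORS - {"n't"}), object)

    vocab = {}
    zipf_p = {}
    for tier, size in spec.vocab_size.items():
        vocab[tier] = np.array([f"w{i:05d}" for i in range(size)], object)
        w = 1.0 / np.arange(1, size + 1) ** spec.zipf_exponent
        zipf_p[tier] = w / w.sum()

    mean_len, sd_len = spec.tokens_per_note
    rows = []
    nid = 0
    for _, pt in cohort.iterrows():
        tier, status = pt["tier"], pt["status"]
        m, s = spec.note_count_params[(tier, status)]
        n_notes = max(1, int(_nbinom_draws(rng, m, s, 1)[0]))
        n_decoy = int(rng.binomial(n_notes, spec.decoy_fraction))
        offsets = list(rng.integers(5, 31, size=n_notes))
        for _ in range(n_decoy):
            offsets.append(int(rng.integers(0, 5)) if rng.random() < 0.5 else int(rng.integers(31, 61)))

        boost = spec.effect_size if status == "case" else 1.0
        r_sem = spec.signal_rate * (boost if spec.signal_mode in ("semantic", "mixed") else 1.0)
        r_cnt = spec.signal_rate * (boost if spec.signal_mode in ("count", "mixed") else 1.0)
        r_calm = spec.signal_rate
        r_neg = spec.negator_rate
        lengths = np.maximum(5, _nbinom_draws(rng, mean_len, sd_len, len(offsets)))
        total = int(lengths.sum())
        u = rng.random(total)
        toks = np.empty(total, dtype=object)
        c1, c2, c3, c4 = r_neg, r_neg + r_sem, r_neg + r_sem + r_cnt, r_neg + r_sem + r_cnt + r_calm
        sel = u < c1
        toks[sel] = rng.choice(negators, size=int(sel.sum()))
        sel = (u >= c1) & (u < c2)
        toks[sel] = rng.choice(sem_terms, size=int(sel.sum()))
        sel = (u >= c2) & (u < c3)
        toks[sel] = rng.choice(cnt_terms, size=int(sel.sum()))
        sel = (u >= c3) & (u < c4)
        toks[sel] = rng.choice(calm_terms, size=int(sel.sum()))
        sel = u >= c4
        toks[sel] = rng.choice(vocab[tier], size=int(sel.sum()), p=zipf_p[tier])

        pos = 0
        for off, length in zip(offsets, lengths):
            text = " ".join(toks[pos:pos + int(length)])
            pos += int(length)
            rows.append({
                "note_id": f"n{nid:07d}",
                "patient_id": pt["patient_id"],
                "note_date": pt["index_date"] - pd.Timedelta(days=int(off)),
                "text": text,
            })
            nid += 1

    truth = {
        "signal_mode": spec.signal_mode,
        "effect_size": spec.effect_size,
        "semantic_signal_terms": list(map(str, sem_terms)),
        "count_signal_terms": list(map(str, cnt_terms)),
        "signal_category": "synthlex.distress",
        "spec": {k: (dict(v) if isinstance(v, dict) else v)
                 for k, v in asdict(spec).items() if k != "note_count_params"},
    }
    return pd.DataFrame(rows), truth


def generate_corpus(spec: GeneratorSpec) -> SyntheticCorpus:
    """Cohort + notes + planted-truth record + the signal lexicon."""
    cohort = generate_cohort(spec)
    notes, truth = generate_notes(cohort, spec)
    return SyntheticCorpus(cohort=cohort, notes=notes, truth=truth, lexicon=signal_lexicon(spec))
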