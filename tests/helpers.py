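"""Independent oracles used by the test suite.

``oracle_decode`` scores every admissible word sequence and frame
segmentation by explicit enumeration — no dynamic programming — so it can
certify the Viterbi search on small instances.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import product

import numpy as np

BOS = "<s>"
EOS = "</s>"
SIL = "sil"


def _transition_logs(mean_frames, phones, default_mean=3.0, p_min=0.05, p_max=0.999):
    out = {}
    for ph in phones:
        m = (mean_frames or {}).get(ph, default_mean)
        p = 1.0 - 1.0 / max(m, 1.0 + 1e-9)
        p = min(max(p, p_min), p_max)
        out[ph] = (math.log(p), math.log(1.0 - p))
    return out


@lru_cache(maxsize=None)
def _compositions(total: int, parts: int) -> tuple:
    """All ways to split `total` frames into `parts` positive integers."""
    if parts == 1:
        return ((total,),)
    out = []
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            out.append((first,) + rest)
    return tuple(out)


def oracle_decode(
    loglik: np.ndarray,
    phones: list[str],
    lexicon: dict[str, tuple[str, ...]],
    lm,
    lm_weight: float = 1.0,
    word_insertion_penalty: float = 0.0,
    mean_frames: dict[str, float] | None = None,
    allow_silence: bool = True,
    max_words: int = 4,
) -> tuple[float, list[str]]:
    """Best (score, word sequence) by exhaustive enumeration.

    Words may be separated (and the phrase bracketed) by optional silence
    runs; each phone occupies at least one frame; scoring matches the
    decoder's conventions (geometric self-loop/advance transitions,
    LM-weighted bigrams at word exits, insertion penalty per word,
    end-of-sentence LM term).
    """
    T = loglik.shape[0]
    col = {p: j for j, p in enumerate(phones)}
    trans = _transition_logs(
        mean_frames, {ph for pr in lexicon.values() for ph in pr} | {SIL}
    )
    words = sorted(lexicon)
    best_score, best_words = -np.inf, None

    def unit_options(m: int):
        """All interleavings of m words with optional silence units."""
        for ws in product(words, repeat=m):
            n_slots = m + 1
            flag_space = product([0, 1], repeat=n_slots) if allow_silence else [(0,) * n_slots]
            for flags in flag_space:
                units = []
                ok = True
                for i in range(m):
                    if flags[i]:
                        units.append((

                            (SIL,), None))
                    units.append((tuple(lexicon[ws[i]]), ws[i]))
                if flags[m]:
                    units.append(((SIL,), None))
                if not units:
                    if allow_silence:
                        units = [((SIL,), None)]
                    else:
                        ok = False
                if ok:
                    yield units, list(ws)

    for m in range(0, max_words + 1):
        for units, ws in unit_options(m):
            chain = [ph for u, _w in units for ph in u]
            L = len(chain)
            if L > T or L == 0:
                continue
            # LM / insertion terms are segmentation-independent
            lm_total = 0.0
            prev = BOS
            for _u, w in units:
                if w is not None:
                    lm_total += lm_weight * lm.logprob(w, prev) + word_insertion_penalty
                    prev = w
            lm_total += lm_weight * lm.logprob(EOS, prev)
            # boundaries between chain elements: advance except at unit starts
            unit_starts = set()
            pos = 0
            for u, _w in units:
                unit_starts.add(pos)
                pos += len(u)
            for alloc in _compositions(T, L):
                s = lm_total
                t = 0
                for k, ph in enumerate(chain):
                    n = alloc[k]
                    sl, al = trans[ph]
                    c = col[ph]
                    for i in range(n):
                        s += loglik[t + i, c]
                    s += (n - 1) * sl
                    if k + 1 < L and (k + 1) not in unit_starts:
                        s += al
                    t += n
                if s > best_score:
                    best_score, best_words = s, ws
        if m == 0 and best_words is None and not allow_silence:
            continue
    return best_score, best_words


def random_toy_instance(rng: np.random.Generator):
    """A random small decoding problem (lexicon, LM corpus, likelihoods)."""
    import b2t

    phone_pool = ["aa", "b", "k", "s", "t"]
    n_words = int(rng.integers(2, 4))
    lexicon = {}
    names = ["go", "hi", "my", "we"][:n_words]
    for w in names:
        plen = int(rng.integers(2, 4))  # >= 2 phones so <= T/2 words fit
        lexicon[w] = tuple(rng.choice(phone_pool, size=plen).tolist())
    corpus = []
    for _ in range(int(rng.integers(2, 5))):
        corpus.append(rng.choice(names, size=int(rng.integers(1, 4))).tolist())
    lm = b2t.estimate_bigram_lm(corpus, vocabulary=names)
    T = int(rng.integers(3, 9))
    phones = sorted(set(ph for pr in lexicon.values() for ph in pr) | {SIL})
    loglik = rng.normal(-3.0, 2.0, size=(T, len(phones)))
    mean_frames = {p: float(rng.uniform(1.5, 4.0)) for p in phones}
    allow_sil = bool(rng.integers(0, 2))
    lam = float(rng.uniform(0.3, 2.0))
    wip = float(rng.uniform(-1.0, 1.0))
    return dict(
        lexicon=lexicon,
        lm=lm,
        loglik=loglik,
        phones=phones,
        mean_frames=mean_frames,
        allow_silence=allow_sil,
        lm_weight=lam,
        word_insertion_penalty=wip,
    )


def decode_both_ways(instance) -> tuple:
    """Run the package decoder and the oracle on the same instance."""
    import b2t
    from b2t.io_session import PronunciationDict

    lex = PronunciationDict({w: [tuple(p)] for w, p in instance["lexicon"].items()})
    graph = b2t.build_search_graph(lex, instance["lm"])
    res = b2t.viterbi_decode(
        instance["loglik"],
        instance["phones"],
        graph,
        lm_weight=instance["lm_weight"],
        word_insertion_penalty=instance["word_insertion_penalty"],
        mean_frames=instance["mean_frames"],
        allow_silence=instance["allow_silence"],
    )
    o_score, o_words = oracle_decode(
        instance["loglik"],
        instance["phones"],
        instance["lexicon"],
        instance["lm"],
        lm_weight=instance["lm_weight"],
        word_insertion_penalty=instance["word_insertion_penalty"],
        mean_frames=instance["mean_frames"],
        allow_silence=instance["allow_silence"],
    )
    return res, o_score, o_words
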