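"""Word-sequence decoding: bigram language model, search graph, Viterbi.

Decoding solves W-hat = argmax_W p(X|W) P(W): the emission likelihoods of
the Gaussian phone models are combined with a word-sequence prior from a
Witten-Bell-smoothed bigram language model over a determinized
phone-prefix tree of the pronunciation lexicon.  The Viterbi search is an
exact max-sum dynamic program over (graph node, previous word) states —
no beam pruning — so its score is reproducible and checkable against
exhaustive enumeration on small instances.

Scale conventions: the language model stores natural-log probabilities
internally and exports/imports the ARPA text format (log10).  The LM
weight multiplies every LM term; the word insertion penalty is added once
per emitted word.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_session import PipelineConfig, PronunciationDict, ValidationError
from .phones import SILENCE

log = logging.getLogger(__name__)

BOS = "<s>"
EOS = "</s>"
NEG_INF = -np.inf


class DecodeError(RuntimeError):
    """No complete path exists through the search graph."""


# ---------------------------------------------------------------------------
# Bigram language model (Witten-Bell interpolation, ARPA import/export)
# ---------------------------------------------------------------------------


class BigramLM:
    """Bigram word model with Witten-Bell smoothing and unigram backoff.

    P(w|h) = c(h,w)/(c(h)+T(h)) + T(h)/(c(h)+T(h)) * P1(w) for observed
    histories h (T(h) = distinct continuations of h), falling back to the
    smoothed unigram P1 for unseen histories.  P1 itself is Witten-Bell
    smoothed against a uniform base over the vocabulary, so every
    vocabulary word has positive probability even with zero training
    count.  For every history the probabilities over vocab + </s> sum to 1.
    """

    def __init__(
        self,
        vocab: list[str],
        log_uni: dict[str, float],
        log_bow: dict[str, float],
        log_bi: dict[tuple[str, str], float],
    ):
        self.vocab = sorted(vocab)
        self._uni = log_uni          # ln P1(w), keys: vocab + EOS
        self._bow = log_bow          # ln backoff weight, keys: BOS + vocab
        self._bi = log_bi            # ln P(w|h) for seen pairs

    # -- scoring -----------------------------------------------------------

    def logprob(self, word: str, history: str) -> float:
        """ln P(word | history); history in {BOS} + vocab, word in vocab + {EOS}."""
        if word not in self._uni:
            raise ValidationError(f"word {word!r} not in LM vocabulary")
        key = (history, word)
        if key in self._bi:
            return self._bi[key]
        bow = self._bow.get(history)
        if bow is None:
            raise ValidationError(f"history {history!r} not in LM vocabulary")
        return bow + self._uni[word]

    def sentence_logprob(self, words: list[str]) -> float:
        h, total = BOS, 0.0
        for w in words:
            total += self.logprob(w, h)
            h = w
        return total + self.logprob(EOS, h)

    def score_matrices(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """(contexts, B, eos): B[c, w] = ln P(vocab[w] | contexts[c]), eos[c] = ln P(</s>|c)."""
        contexts = [BOS] + self.vocab
        B = np.empty((len(contexts), len(self.vocab)))
        eos = np.empty(len(contexts))
        for ci, h in enumerate(contexts):
            for wi, w in enumerate(self.vocab):
                B[ci, wi] = self.logprob(w, h)
            eos[ci] = self.logprob(EOS, h)
        return contexts, B, eos

    # -- ARPA text format --------------------------------------------------

    def to_arpa(self) -> str:
        ln10 = math.log(10.0)
        uni_words = self.vocab + [EOS]
        lines = ["\\data\\"]
        lines.append(f"ngram 1={len(uni_words) + 1}")  # + <s>
        lines.append(f"ngram 2={len(self._bi)}")
        lines.append("")
        lines.append("\\1-grams:")
        lines.append(f"-99\t{BOS}\t{self._bow[BOS] / ln10:.7f}")
        for w in uni_words:
            bow = self._bow.get(w)
            tail = f"\t{bow / ln10:.7f}" if bow is not None else ""
            lines.append(f"{self._uni[w] / ln10:.7f}\t{w}{tail}")
        lines.append("")
        lines.append("\\2-grams:")
        for (h, w), lp in sorted(self._bi.items()):
            lines.append(f"{lp / ln10:.7f}\t{h} {w}")
        lines.append("")
        lines.append("\\end\\")
        return "\n".join(lines) + "\n"

    def save_arpa(self, path: str | Path) -> None:
        Path(path).write_text(self.to_arpa(), encoding="utf-8")

    @classmethod
    def from_arpa(cls, text: str) -> "BigramLM":
        ln10 = math.log(10.0)
        section = None
        uni: dict[str, float] = {}
        bow: dict[str, float] = {}
        bi: dict[tuple[str, str], float] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("ngram ") or line == "\\data\\":
                continue
            if line in ("\\1-grams:", "\\2-grams:", "\\end\\"):
                section = line
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if section == "\\1-grams:":
                lp, word = float(parts[0]), parts[1]
                if word != BOS:
                    uni[word] = lp * ln10
                if len(parts) > 2:
                    bow[word] = float(parts[2]) * ln10
            elif section == "\\2-grams:":
                lp = float(parts[0]) * ln10
                h, w = parts[1].split() if len(parts) == 2 else (parts[1], parts[2])
                bi[(h, w)] = lp
        vocab = sorted(w for w in uni if w != EOS)
        return cls(vocab, uni, bow, bi)

    @classmethod
    def load_arpa(cls, path: str | Path) -> "BigramLM":
        return cls.from_arpa(Path(path).read_text(encoding="utf-8"))


def estimate_bigram_lm(
    sentences: list[list[str]], vocabulary: list[str] | None = None
) -> BigramLM:
    """Estimate a Witten-Bell bigram LM from tokenized sentences.

    ``vocabulary`` restricts the model (tokens outside it are dropped
    before counting — the restricted-dictionary evaluation relies on
    this); by default the observed words define the vocabulary.
    """
    if not sentences or all(not s for s in sentences):
        raise ValidationError("empty corpus")
    sents = [[w.lower() for w in s] for s in sentences]
    if vocabulary is None:
        vocab = sorted({w for s in sents for w in s})
    else:
        vocab = sorted({w.lower() for w in vocabulary})
        sents = [[w for w in s if w in set(vocab)] for s in sents]
    if not vocab:
        raise ValidationError("empty vocabulary")
    events = vocab + [EOS]

    c_uni: dict[str, int] = {w: 0 for w in events}
    c_bi: dict[tuple[str, str], int] = {}
    c_hist: dict[str, int] = {}
    for s in sents:
        tokens = s + [EOS]
        h = BOS
        for w in tokens:
            c_uni[w] += 1
            c_bi[(h, w)] = c_bi.get((h, w), 0) + 1
            c_hist[h] = c_hist.get(h, 0) + 1
            h = w if w != EOS else BOS

    # smoothed unigram: Witten-Bell against a uniform base over vocab+EOS
    N = sum(c_uni.values())
    T_u = sum(1 for v in c_uni.values() if v > 0)
    V = len(events)
    log_uni = {
        w: math.log((c + T_u / V) / (N + T_u)) for w, c in c_uni.items()
    }

    # bigrams: interpolated Witten-Bell; store full interpolated prob for
    # seen pairs, backoff weight T/(c+T) routes unseen words to the unigram
    log_bow: dict[str, float] = {}
    log_bi: dict[tuple[str, str], float] = {}
    histories = [BOS] + vocab
    types: dict[str, int] = {}
    for (h, _w), c in c_bi.items():
        if c > 0:
            types[h] = types.get(h, 0) + 1
    for h in histories:
        ch = c_hist.get(h, 0)
        th = types.get(h, 0)
        if ch == 0:
            log_bow[h] = 0.0  # unseen history: pure unigram
            continue
        log_bow[h] = math.log(th / (ch + th))
        for w in events:
            c = c_bi.get((h, w), 0)
            if c > 0:
                p = (c + th * math.exp(log_uni[w])) / (ch + th)
                log_bi[(h, w)] = math.log(p)
    return BigramLM(vocab, log_uni, log_bow, log_bi)


# ---------------------------------------------------------------------------
# Search graph
# ---------------------------------------------------------------------------


@dataclass
class SearchGraph:
    """Determinized phone-prefix tree over the lexicon with word-exit arcs.

    Nodes are emitting phone states; shared word prefixes are merged so at
    most one advance arc exists per (node, phone).  ``parent[i] == -1``
    marks word-initial nodes (children of the virtual root).  ``word_end``
    lists the word indices whose pronunciation ends at each node
    (homophones share an end node).  LM-weighted word-exit arcs and the
    optional silence loop are realised inside the Viterbi DP.
    """

    phone: list[str]
    parent: np.ndarray
    word_end: list[list[int]]
    words: list[str]
    lm: BigramLM
    min_duration: int = 1

    @property
    def n_nodes(self) -> int:
        return len(self.phone)

    def canonical(self) -> tuple:
        """Canonical serialization — equal for isomorphic rebuilds."""
        return (
            tuple(self.phone),
            tuple(int(p) for p in self.parent),
            tuple(tuple(w) for w in self.word_end),
            tuple(self.words),
            self.min_duration,
        )


def build_search_graph(
    lexicon: PronunciationDict, lm: BigramLM, min_duration: int = 1
) -> SearchGraph:
    """Build the prefix tree (words in lexicographic order, phones in order)."""
    if len(lexicon) == 0:
        raise ValidationError("empty lexicon")
    words = lexicon.words
    lm_vocab = set(lm.vocab)
    for w in words:
        if w not in lm_vocab:
            raise ValidationError(f"word {w!r} missing from the language model vocabulary")

    phone: list[str] = []
    parent: list[int] = []
    word_end: list[list[int]] = []
    children: list[dict[str, int]] = []  # per node: phone -> child
    root_children: dict[str, int] = {}

    def new_node(ph: str, par: int) -> int:
        phone.append(ph)
        parent.append(par)
        word_end.append([])
        children.append({})
        return len(phone) - 1

    for wi, w in enumerate(words):
        for pron in lexicon[w]:
            expanded: list[str] = []
            for ph in pron:
                expanded.extend([ph] * min_duration)
            node = -1
            table = root_children
            for ph in expanded:
                if ph in table:
                    node = table[ph]
                else:
                    node = new_node(ph, node)
                    table[ph] = node
                table = children[node]
            if wi not in word_end[node]:
                word_end[node].append(wi)
    return SearchGraph(
        phone, np.asarray(parent, dtype=int), word_end, words, lm, min_duration
    )


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------


@dataclass
class DecodeResult:
    words: list[str]
    phone_sequence: list[str]
    frame_path: list[str]
    score: float
    components: dict[str, float] = field(default_factory=dict)


def phone_transition_logprobs(
    phones: list[str],
    mean_frames: dict[str, float] | None,
    cfg: PipelineConfig,
) -> dict[str, tuple[float, float]]:
    """(ln p_self, ln p_advance) per phone from expected durations.

    A phone whose training segments last m frames on average gets
    self-loop probability p = 1 - 1/m (geometric duration with mean m),
    clipped away from 0 and 1.
    """
    out = {}
    for ph in phones:
        m = (mean_frames or {}).get(ph, cfg.default_mean_phone_frames)
        p = 1.0 - 1.0 / max(m, 1.0 + 1e-9)
        p = min(max(p, cfg.min_self_loop_prob), cfg.max_self_loop_prob)
        out[ph] = (math.log(p), math.log(1.0 - p))
    return out


def viterbi_decode(
    loglik: np.ndarray,
    loglik_phones: list[str],
    graph: SearchGraph,
    lm_weight: float = 1.0,
    word_insertion_penalty: float = 0.0,
    mean_frames: dict[str, float] | None = None,
    allow_silence: bool = True,
    cfg: PipelineConfig | None = None,
) -> DecodeResult:
    """Exact max-sum Viterbi over (graph node, previous word) states.

    Scores combine per-frame emission log-likelihoods, per-phone
    self-loop/advance transition log-probabilities, LM-weighted bigram
    terms at word exits (plus the insertion penalty) and the end-of-
    sentence LM term.  Tie-breaking is deterministic: staying in a node
    beats advancing beats entering a new word, contexts resolve in index
    order and vocabulary in lexicographic order.  Raises ``DecodeError``
    when no complete path exists.
    """
    cfg = cfg or PipelineConfig()
    T = loglik.shape[0]
    if T < 1:
        raise DecodeError("no frames to decode")
    col = {p: j for j, p in enumerate(loglik_phones)}
    for ph in set(graph.phone):
        if ph not in col:
            raise ValidationError(f"graph phone {ph!r} has no likelihood column")
    if allow_silence and SILENCE not in col:
        raise ValidationError("silence decoding requested but no 'sil' likelihood column")

    n_nodes = graph.n_nodes
    sil_node = n_nodes if allow_silence else -1
    n_all = n_nodes + (1 if allow_silence else 0)
    node_phone = list(graph.phone) + ([SILENCE] if allow_silence else [])
    trans = phone_transition_logprobs(sorted(set(node_phone)), mean_frames, cfg)
    self_log = np.array([trans[p][0] for p in node_phone])
    adv_log = np.array([trans[p][1] for p in node_phone])
    emis_col = np.array([col[p] for p in node_phone])
    parent = np.concatenate([graph.parent, [-1]]) if allow_silence else graph.parent
    is_first = parent == -1

    contexts, Bm, eos = graph.lm.score_matrices()
    lam = lm_weight
    B = lam * Bm
    eos = lam * eos
    n_ctx = len(contexts)
    V = len(graph.lm.vocab)
    word_ctx = {w: i for i, w in enumerate(contexts)}  # vocab word -> ctx index
    word_idx = {w: i for i, w in enumerate(graph.lm.vocab)}
    # end-node lists per word index (in graph.words order == lexicographic)
    ends_of_word: list[list[int]] = [[] for _ in graph.words]
    for n, wids in enumerate(graph.word_end):
        for wi in wids:
            ends_of_word[wi].append(n)

    # Two root channels keep silence units from chaining: entries into the
    # silence state read R_word (last unit was a word, or phrase start),
    # entries into words read R_all = max(R_word, silence exit).
    S = np.full((n_all, n_ctx), NEG_INF)
    bp_kind = np.zeros((T, n_all, n_ctx), dtype=np.uint8)  # 0 self, 1 adv, 2 root
    root_src_node = np.full((T, n_ctx), -3, dtype=np.int32)
    root_src_ctx = np.full((T, n_ctx), -3, dtype=np.int32)
    R_word = np.full(n_ctx, NEG_INF)
    R_word[0] = 0.0  # sentence start
    R_all = R_word.copy()
    word_src_node = np.full((T, n_ctx), -3, dtype=np.int32)
    word_src_ctx = np.full((T, n_ctx), -3, dtype=np.int32)
    root_src_node[0, 0] = -2  # initial marker
    root_src_ctx[0, 0] = -2
    word_src_node[0, 0] = -2
    word_src_ctx[0, 0] = -2

    has_parent = np.nonzero(~is_first)[0]
    first_word_nodes = np.nonzero(is_first[:n_nodes])[0]

    for t in range(T):
        emis = loglik[t][emis_col][:, None]  # n_all x 1
        best = S + self_log[:, None]  # self-loop (NEG_INF at t=0)
        kind = np.zeros((n_all, n_ctx), dtype=np.uint8)
        if has_parent.size:
            cand = S[parent[has_parent]] + adv_log[parent[has_parent]][:, None]
            cur = best[has_parent]
            upd = cand > cur
            cur[upd] = cand[upd]
            best[has_parent] = cur
            kslice = kind[has_parent]
            kslice[upd] = 1
            kind[has_parent] = kslice
        if first_word_nodes.size:
            cand = np.broadcast_to(R_all, (first_word_nodes.size, n_ctx))
            cur = best[first_word_nodes]
            upd = cand > cur
            cur = np.where(upd, cand, cur)
            best[first_word_nodes] = cur
            kslice = kind[first_word_nodes]
            kslice[upd] = 2
            kind[first_word_nodes] = kslice
        if allow_silence:
            upd = R_word > best[sil_node]
            best[sil_node][upd] = R_word[upd]
            kind[sil_node][upd] = 2
        S = best + emis
        bp_kind[t] = kind

        if t == T - 1:
            break
        # exits after frame t feed entries at frame t+1
        R_word = np.full(n_ctx, NEG_INF)
        src_n = np.full(n_ctx, -3, dtype=np.int32)
        src_c = np.full(n_ctx, -3, dtype=np.int32)
        for wi, w in enumerate(graph.words):
            ci_new = word_ctx[w]
            bcol = B[:, word_idx[w]]
            for e in ends_of_word[wi]:
                cand = S[e] + bcol + word_insertion_penalty
                c_best = int(np.argmax(cand))
                if cand[c_best] > R_word[ci_new]:
                    R_word[ci_new] = cand[c_best]
                    src_n[ci_new] = e
                    src_c[ci_new] = c_best
        word_src_node[t + 1] = src_n
        word_src_ctx[t + 1] = src_c
        R_all = R_word.copy()
        src_n_all = src_n.copy()
        src_c_all = src_c.copy()
        if allow_silence:
            upd = S[sil_node] > R_all
            R_all[upd] = S[sil_node][upd]
            src_n_all[upd] = sil_node
            src_c_all[upd] = np.nonzero(upd)[0]
        root_src_node[t + 1] = src_n_all
        root_src_ctx[t + 1] = src_c_all

    # termination
    best_score = NEG_INF
    final: tuple | None = None  # (node, ctx, word or None)
    for wi, w in enumerate(graph.words):
        ci_new = word_ctx[w]
        bcol = B[:, word_idx[w]]
        for e in ends_of_word[wi]:
            cand = S[e] + bcol + word_insertion_penalty + eos[ci_new]
            c_best = int(np.argmax(cand))
            if cand[c_best] > best_score:
                best_score = cand[c_best]
                final = (e, c_best, w)
    if allow_silence:
        cand = S[sil_node] + eos
        c_best = int(np.argmax(cand))
        if cand[c_best] > best_score:
            best_score = cand[c_best]
            final = (sil_node, c_best, None)
    if final is None or not np.isfinite(best_score):
        raise DecodeError("no complete path through the search graph")

    # traceback (accumulating the score decomposition as we walk back)
    node, ctx, last_word = final
    comp = {"emission": 0.0, "transition": 0.0, "lm": 0.0, "insertion": 0.0}
    if last_word is not None:
        comp["lm"] += B[ctx, word_idx[last_word]] + eos[word_ctx[last_word]]
        comp["insertion"] += word_insertion_penalty
    else:
        comp["lm"] += eos[ctx]
    words_rev: list[str] = [] if last_word is None else [last_word]
    frame_path: list[str] = [""] * T
    phone_seq_rev: list[str] = []
    t = T - 1
    while True:
        frame_path[t] = node_phone[node]
        comp["emission"] += float(loglik[t, emis_col[node]])
        k = int(bp_kind[t, node, ctx])
        if k == 0:
            comp["transition"] += float(self_log[node])
        elif k == 1:
            phone_seq_rev.append(node_phone[node])
            node = int(parent[node])
            comp["transition"] += float(adv_log[node])
        else:  # entered from root at frame t
            phone_seq_rev.append(node_phone[node])
            # silence entries read the word-exit root channel only
            if node == sil_node:
                src = int(word_src_node[t, ctx])
                prev_ctx = int(word_src_ctx[t, ctx])
            else:
                src = int(root_src_node[t, ctx])
                prev_ctx = int(root_src_ctx[t, ctx])
            if src == -2:
                break  # initial entry at t == 0
            if src != sil_node:
                # the context word names the word that exited at t-1
                w = contexts[ctx]
                words_rev.append(w)
                comp["lm"] += float(B[prev_ctx, word_idx[w]])
                comp["insertion"] += word_insertion_penalty
            node, ctx = src, prev_ctx
        t -= 1
    words = list(reversed(words_rev))
    phone_sequence = list(reversed(phone_seq_rev))
    return DecodeResult(words, phone_sequence, frame_path, float(best_score), comp)


def decode_phrase(
    model_set,
    F_reduced: np.ndarray,
    lexicon: PronunciationDict,
    lm: BigramLM,
    cfg: PipelineConfig | None = None,
    mean_frames: dict[str, float] | None = None,
) -> DecodeResult:
    """Emission likelihoods -> Viterbi word sequence for one phrase."""
    from .phone_models import log_likelihood_matrix

    cfg = cfg or PipelineConfig()
    loglik, phones = log_likelihood_matrix(model_set, F_reduced)
    graph = build_search_graph(lexicon, lm, cfg.min_phone_duration_frames)
    return viterbi_decode(
        loglik,
        phones,
        graph,
        lm_weight=cfg.lm_weight,
        word_insertion_penalty=cfg.word_insertion_penalty,
        mean_frames=mean_frames,
        allow_silence=cfg.allow_silence_in_decoding,
        cfg=cfg,
    )
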