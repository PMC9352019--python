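"""Experiment harness: row-size/fill sweeps, occlusion, relaxation.

Two accounting levels are reported at every sweep point:

* **per register** — each class's register is scored as a one-vs-rest
  detector: a true positive is an own-class cue it accepts, a false
  positive an other-class cue it accepts, a false negative an own-class
  cue it rejects.  Both macro (mean of per-register ratios) and pooled
  (ratios of summed counts) variants are emitted.
* **system** — each cue yields one decision through the entropy filter:
  rejected by every register counts as a system false negative; accepted
  with the wrong winning class counts as a false negative for the true
  class *and* a false positive for the accepting class.

Fill sweeps use nested prefixes of a per-class seeded shuffle, so
acceptance (hence recall) is exactly monotone in the fill fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AMRGrid
from .quantize import LevelQuantizer
from .synthetic import Corpus
from .codec import CodecSpec, toy_codec

__all__ = [
    "EvalReport",
    "RetrievalGrid",
    "register_sweep",
    "fill_sweep",
    "relaxation_sweep",
    "occlude_bottom_half",
    "occlude_bars",
    "occluded_fraction",
    "save_retrieval_mosaic",
]

ROW_SIZES = tuple(2**p for p in range(10))  # 1 .. 512
FILL_FRACTIONS = (1, 2, 4, 8, 16, 32, 64, 100)
RELAXATIONS = (0, 1, 2, 3)


@dataclass
class EvalReport:
    """Sweep results: one row of ``table`` per sweep point.

    ``per_register`` holds the long-form per-class counts behind the
    aggregate columns, so every headline number can be recomputed from
    raw TP/FP/FN tallies.
    """

    table: pd.DataFrame
    per_register: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "meta": self.meta,
            "points": self.table.to_dict(orient="records"),
        }


@dataclass
class RetrievalGrid:
    """Table-of-retrievals artifact for the occlusion experiments.

    ``labels[k]`` is a DataFrame with one row per fill fraction and one
    column per class; a cell holds the winning class of the occluded
    representative cue or NaN where every register rejected (a blank
    cell).  ``images[(k, fraction, class)]`` is the decoded retrieved
    image, present only for accepted cues.
    """

    labels: dict
    images: dict


# ----------------------------------------------------------------------
# tallies

def _safe_div(a, b):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(b > 0, a / np.where(b > 0, b, 1), np.nan)
    return out


def _tally(registers: dict, classes: np.ndarray, Xq: np.ndarray, y: np.ndarray, k: int) -> dict:
    """Score a set of cues against a bank of registers at relaxation k."""
    T = Xq.shape[0]
    C = len(classes)
    acc = np.zeros((T, C), dtype=bool)
    for j, c in enumerate(classes):
        acc[:, j], _ = registers[c].recognize_batch(Xq, k)
    ent = np.array([registers[c].entropy() for c in classes])
    own = y[:, None] == np.asarray(classes)[None, :]

    tp_r = (acc & own).sum(axis=0)
    fp_r = (acc & ~own).sum(axis=0)
    fn_r = (~acc & own).sum(axis=0)

    any_acc = acc.any(axis=1)
    masked = np.where(acc, ent[None, :], np.inf)
    winner = np.asarray(classes)[np.argmin(masked, axis=1)]
    correct = any_acc & (winner == y)
    wrong = any_acc & (winner != y)
    sys_tp = int(correct.sum())
    sys_fp = int(wrong.sum())
    sys_fn = int((~any_acc).sum()) + sys_fp  # wrong winner double-counts

    prec_r = _safe_div(tp_r, tp_r + fp_r)
    rec_r = _safe_div(tp_r, tp_r + fn_r)
    return {
        "entropy_mean": float(ent.mean()),
        "macro_precision": float(np.nanmean(prec_r)) if not np.all(np.isnan(prec_r)) else np.nan,
        "macro_recall": float(np.nanmean(rec_r)) if not np.all(np.isnan(rec_r)) else np.nan,
        "pooled_precision": float(_safe_div(tp_r.sum(), tp_r.sum() + fp_r.sum())),
        "pooled_recall": float(_safe_div(tp_r.sum(), tp_r.sum() + fn_r.sum())),
        "system_precision": float(_safe_div(sys_tp, sys_tp + sys_fp)),
        "system_recall": float(_safe_div(sys_tp, sys_tp + sys_fn)),
        "mean_accepting": float(acc.sum(axis=1).mean()),
        "accepted_cues": int(any_acc.sum()),
        "reg_tp": int(tp_r.sum()),
        "reg_fp": int(fp_r.sum()),
        "reg_fn": int(fn_r.sum()),
        "system_tp": sys_tp,
        "system_fp": sys_fp,
        "system_fn": sys_fn,
        "_per_register": pd.DataFrame(
            {
                "class": classes,
                "tp": tp_r,
                "fp": fp_r,
                "fn": fn_r,
                "precision": prec_r,
                "recall": rec_r,
                "entropy": ent,
            }
        ),
        "_acc": acc,
        "_winner": winner,
        "_any_acc": any_acc,
    }


def _check_partitions(corpus: Corpus) -> None:
    for name in ("train", "remembered", "test"):
        if len(getattr(corpus, name)) == 0:
            raise ValueError(f"corpus partition {name!r} is empty")


def _registers_for(classes, n, m) -> dict:
    return {c: AMRGrid(n, m) for c in classes}


# ----------------------------------------------------------------------
# sweeps on feature corpora

def register_sweep(corpus: Corpus, m_values=ROW_SIZES, k: int = 0) -> EvalReport:
    """Row-size sweep: quantize, fill, and score once per table height m.

    For each value of m the quantizer is calibrated on the training
    partition, the full remembered partition is stored, and every test
    cue is scored at relaxation ``k``.
    """
    _check_partitions(corpus)
    classes = np.unique(corpus.remembered.y)
    rows, per_reg = [], []
    for m in m_values:
        q = LevelQuantizer(m=m).fit(corpus.train.X)
        Xrem = q.transform(corpus.remembered.X)
        Xtest = q.transform(corpus.test.X)
        registers = _registers_for(classes, Xrem.shape[1], m)
        for f, c in zip(Xrem, corpus.remembered.y):
            registers[c].register(f)
        t = _tally(registers, classes, Xtest, corpus.test.y, k)
        pr = t.pop("_per_register")
        for key in ("_acc", "_winner", "_any_acc"):
            t.pop(key)
        pr.insert(0, "m", m)
        per_reg.append(pr)
        rows.append({"m": m, **t})
    return EvalReport(
        pd.DataFrame(rows),
        pd.concat(per_reg, ignore_index=True),
        meta={"sweep": "rows", "k": k, "m_values": list(m_values)},
    )


def _nested_prefixes(y: np.ndarray, rng: np.random.Generator) -> dict:
    """Per-class index order, shuffled once so prefixes nest across fractions."""
    orders = {}
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        orders[c] = idx[rng.permutation(len(idx))]
    return orders


def _prefix_len(total: int, fraction_pct: float) -> int:
    return max(1, int(np.ceil(fraction_pct / 100.0 * total)))


def fill_sweep(
    corpus: Corpus,
    m_fixed: int = 64,
    fractions=FILL_FRACTIONS,
    k: int = 0,
    seed: int = 0,
) -> EvalReport:
    """Fill-fraction sweep at a fixed table height.

    The remembered partition is shuffled per class once (seeded) and
    each fraction stores the corresponding prefix, so contents are
    nested across fractions and acceptance is exactly monotone.
    """
    _check_partitions(corpus)
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be increasing")
    classes = np.unique(corpus.remembered.y)
    q = LevelQuantizer(m=m_fixed).fit(corpus.train.X)
    Xrem = q.transform(corpus.remembered.X)
    Xtest = q.transform(corpus.test.X)
    rng = np.random.default_rng(seed)
    orders = _nested_prefixes(corpus.remembered.y, rng)
    registers = _registers_for(classes, Xrem.shape[1], m_fixed)
    done = {c: 0 for c in classes}
    rows, per_reg = [], []
    for frac in fractions:
        for c in classes:
            upto = _prefix_len(len(orders[c]), frac)
            for idx in orders[c][done[c] : upto]:
                registers[c].register(Xrem[idx])
            done[c] = max(done[c], upto)
        t = _tally(registers, classes, Xtest, corpus.test.y, k)
        pr = t.pop("_per_register")
        for key in ("_acc", "_winner", "_any_acc"):
            t.pop(key)
        pr.insert(0, "fill_fraction", frac)
        per_reg.append(pr)
        rows.append({"fill_fraction": frac, "m": m_fixed, **t})
    return EvalReport(
        pd.DataFrame(rows),
        pd.concat(per_reg, ignore_index=True),
        meta={"sweep": "fill", "m": m_fixed, "k": k, "seed": seed},
    )


# ----------------------------------------------------------------------
# occlusion operators

def occlude_bottom_half(img: np.ndarray) -> np.ndarray:
    """Zero the bottom half of the image (14 of 28 rows); idempotent."""
    img = np.asarray(img, dtype=float)
    out = img.copy()
    h = img.shape[0]
    out[h - h // 2 :, :] = 0.0
    return out


def occlude_bars(
    img: np.ndarray, bar_height: int = 3, gap: int = 2, phase: int = 0
) -> np.ndarray:
    """Zero periodic horizontal bars; defaults cover 18/28 rows (64%)."""
    if bar_height < 1 or gap < 1:
        raise ValueError("bar_height and gap must be positive")
    if phase < 0:
        raise ValueError("phase must be non-negative")
    img = np.asarray(img, dtype=float)
    out = img.copy()
    h = img.shape[0]
    period = bar_height + gap
    r = phase
    while r < h:
        out[r : min(r + bar_height, h), :] = 0.0
        r += period
    return out


def occluded_fraction(occluder, shape=(28, 28)) -> float:
    """Fraction of pixels an occluder zeroes on an all-ones image."""
    ones = np.ones(shape)
    return float((occluder(ones) == 0).mean())


# ----------------------------------------------------------------------
# occlusion / relaxation sweep on image corpora

def relaxation_sweep(
    corpus_images: Corpus,
    m_fixed: int = 64,
    ks=RELAXATIONS,
    occluder=occlude_bottom_half,
    fractions=FILL_FRACTIONS,
    codec: CodecSpec = toy_codec,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[EvalReport, RetrievalGrid]:
    """Occluded-cue retrieval at graded relaxation and fill levels.

    Every test image is occluded, encoded, quantized and queried at
    each relaxation ``k`` and each fill fraction.  Besides the metric
    table, a table-of-retrievals artifact is emitted: per relaxation, a
    (fraction × class) grid holding the winning label and the decoded
    retrieved image of one representative cue per class, with blanks
    where the cue was rejected.
    """
    _check_partitions(corpus_images)
    rng = np.random.default_rng(seed + 1) if rng is None else rng
    classes = np.unique(corpus_images.remembered.y)

    enc = lambda imgs: np.stack([codec.encode(im) for im in imgs])
    q = LevelQuantizer(m=m_fixed).fit(enc(corpus_images.train.X))
    Xrem = q.transform(enc(corpus_images.remembered.X))
    occluded = np.stack([occluder(im) for im in corpus_images.test.X])
    Xtest = q.transform(enc(occluded))
    y_test = corpus_images.test.y

    # one representative occluded cue per class for the retrieval grid
    rep_idx = {c: int(np.nonzero(y_test == c)[0][0]) for c in classes if (y_test == c).any()}

    shuffle_rng = np.random.default_rng(seed)
    orders = _nested_prefixes(corpus_images.remembered.y, shuffle_rng)
    registers = _registers_for(classes, Xrem.shape[1], m_fixed)
    done = {c: 0 for c in classes}

    rows, per_reg = [], []
    labels = {k: pd.DataFrame(index=list(fractions), columns=list(classes), dtype=object) for k in ks}
    images = {}
    for frac in fractions:
        for c in classes:
            upto = _prefix_len(len(orders[c]), frac)
            for idx in orders[c][done[c] : upto]:
                registers[c].register(Xrem[idx])
            done[c] = max(done[c], upto)
        ent = {c: registers[c].entropy() for c in classes}
        for k in ks:
            t = _tally(registers, classes, Xtest, y_test, k)
            acc, winner, any_acc = t.pop("_acc"), t.pop("_winner"), t.pop("_any_acc")
            pr = t.pop("_per_register")
            pr.insert(0, "k", k)
            pr.insert(0, "fill_fraction", frac)
            per_reg.append(pr)
            rows.append({"fill_fraction": frac, "k": k, "m": m_fixed, **t})
            for c, i in rep_idx.items():
                if not any_acc[i]:
                    continue
                win = winner[i]
                labels[k].loc[frac, c] = win
                outcome = registers[win].retrieve(Xtest[i], k, rng)
                if outcome.accepted:
                    feats = q.inverse_transform(outcome.function.astype(float))
                    images[(k, frac, c)] = codec.decode(feats)
    report = EvalReport(
        pd.DataFrame(rows),
        pd.concat(per_reg, ignore_index=True),
        meta={
            "sweep": "relaxation",
            "m": m_fixed,
            "ks": list(ks),
            "fractions": list(fractions),
            "occluder": getattr(occluder, "__name__", str(occluder)),
            "seed": seed,
        },
    )
    return report, RetrievalGrid(labels, images)


def save_retrieval_mosaic(
    grid: RetrievalGrid, k: int, path: str, image_size: int = 28
) -> None:
    """Render one relaxation level of a retrieval grid as a PNG mosaic.

    Rows are fill fractions, columns are classes; rejected cues stay
    blank, mirroring the tables of the occlusion experiments.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = grid.labels[k]
    fractions, classes = list(table.index), list(table.columns)
    fig, axes = plt.subplots(
        len(fractions),
        len(classes),
        figsize=(0.35 * len(classes), 0.35 * len(fractions)),
        squeeze=False,
    )
    for r, frac in enumerate(fractions):
        for c, cls in enumerate(classes):
            ax = axes[r][c]
            ax.set_xticks([])
            ax.set_yticks([])
            img = grid.images.get((k, frac, cls))
            if img is not None:
                ax.imshow(img, cmap="gray_r", vmin=0, vmax=1)
            else:
                ax.set_facecolor("white")
            for spine in ax.spines.values():
                spine.set_linewidth(0.2)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
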