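"""Quantitative circuit analyses: modulation classification, cross/within-
modulation weight ratios, input-layer ratios, weight summaries, persistence of
strong connections, and KS comparisons.

Modulation labels: a unit (or input channel) is '1'-modulated if its mean
firing rate over all target-'1' milliseconds exceeds its rate over target-'0'
milliseconds, '0'-modulated for the converse; silent units and exact ties are
left unclassified and excluded from all partitions.  All ratios are computed
on absolute weights of active (nonzero) connections only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import WeightSet

UNCLASSIFIED = -1


@dataclass
class ModulationProfile:
    """Per-unit (and optionally per-channel) preferred-label assignment."""

    unit_label: np.ndarray                 # (n_units,) in {0, 1, UNCLASSIFIED}
    rate0: np.ndarray = None               # mean rate during '0' ms, spikes/ms
    rate1: np.ndarray = None
    channel_label: np.ndarray = None       # (n_channels,) same coding

    @property
    def n_units(self) -> int:
        return len(self.unit_label)

    def counts(self) -> dict:
        lab = self.unit_label
        return {"n0": int((lab == 0).sum()), "n1": int((lab == 1).sum()),
                "unclassified": int((lab == UNCLASSIFIED).sum())}


@dataclass
class RatioSummary:
    """Across/within-modulation mean-|weight| ratios per connection class."""

    within_mean: dict = field(default_factory=dict)
    across_mean: dict = field(default_factory=dict)
    ratio: dict = field(default_factory=dict)
    epoch: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": k, "within_mean": self.within_mean.get(k, np.nan),
                 "across_mean": self.across_mean.get(k, np.nan),
                 "ratio": self.ratio.get(k, np.nan), "epoch": self.epoch}
                for k in self.ratio]
        return pd.DataFrame(rows)


def _label_from_rates(r0: np.ndarray, r1: np.ndarray) -> np.ndarray:
    label = np.full(r0.shape, UNCLASSIFIED, dtype=np.int64)
    label[r1 > r0] = 1
    label[r0 > r1] = 0
    label[(r0 == 0) & (r1 == 0)] = UNCLASSIFIED  # silent
    return label


def _mean_rates_by_label(z: np.ndarray, targets: np.ndarray, dt: float = 1.0):
    """Pooled mean rate per row of z during target-0 and target-1 milliseconds.

    ``z``: (n_trials, n_rows, T); ``targets``: (n_trials, T) binary label series.
    """
    z = np.asarray(z, float)
    targets = np.asarray(targets)
    m1 = targets > 0.5
    n1 = m1.sum()
    n0 = (~m1).sum()
    if n0 == 0 or n1 == 0:
        raise ValueError("need at least one ms of each label across the evaluation set")
    r1 = np.einsum("brt,bt->r", z, m1.astype(float)) / n1 / dt
    r0 = np.einsum("brt,bt->r", z, (~m1).astype(float)) / n0 / dt
    return r0, r1


def classify_modulation(rasters: np.ndarray, targets: np.ndarray,
                        input_spikes: np.ndarray | None = None,
                        dt: float = 1.0) -> ModulationProfile:
    """Assign preferred labels from evaluation trials.

    ``rasters``: (n_trials, n_units, T) spike records; ``targets``:
    (n_trials, T) binary label series.  If ``input_spikes`` (n_trials,
    n_channels, T) is given, channels are classified by the same procedure.
    """
    r0, r1 = _mean_rates_by_label(rasters, targets, dt)
    prof = ModulationProfile(unit_label=_label_from_rates(r0, r1), rate0=r0, rate1=r1)
    if input_spikes is not None:
        c0, c1 = _mean_rates_by_label(input_spikes, targets, dt)
        prof.channel_label = _label_from_rates(c0, c1)
    return prof


def random_modulation_profile(n_e: int, n_i: int, rng: np.random.Generator,
                              e_counts: tuple = (27, 194),
                              i_counts: tuple = (21, 22)) -> ModulationProfile:
    """Random label assignment at trained-state population proportions.

    ``e_counts``/``i_counts`` are the ('0'-labeled, '1'-labeled) counts for the
    reference population sizes (240 e, 60 i); they are rescaled proportionally
    for other sizes, with the remainder left unclassified.  Used as the null
    for ratio calibration.
    """
    def assign(n, counts, ref):
        k0 = min(int(round(counts[0] * n / ref)), n)
        k1 = min(int(round(counts[1] * n / ref)), n - k0)
        lab = np.full(n, UNCLASSIFIED, dtype=np.int64)
        perm = rng.permutation(n)
        lab[perm[:k0]] = 0
        lab[perm[k0:k0 + k1]] = 1
        return lab

    label = np.concatenate([assign(n_e, e_counts, 240), assign(n_i, i_counts, 60)])
    return ModulationProfile(unit_label=label)


def _pair_ratio(W: np.ndarray, mask: np.ndarray, pre_sel: np.ndarray,
                post_sel: np.ndarray, pre_lab: np.ndarray, post_lab: np.ndarray):
    """Mean |w| of within- and across-modulation active connections."""
    classified_pre = (pre_lab >= 0) & pre_sel
    classified_post = (post_lab >= 0) & post_sel
    sel = mask & classified_pre[:, None] & classified_post[None, :]
    same = pre_lab[:, None] == post_lab[None, :]
    w = np.abs(W)
    within = w[sel & same]
    across = w[sel & ~same]
    wm = within.mean() if within.size else np.nan
    am = across.mean() if across.size else np.nan
    return wm, am


def cross_within_ratio(W_rec: np.ndarray, profile: ModulationProfile,
                       mask: np.ndarray | None = None,
                       sign: np.ndarray | None = None,
                       epoch: int | None = None) -> RatioSummary:
    """Across/within-modulation mean-|weight| ratios of the recurrent layer.

    Reported per connection class (ee, ei, ie, ii) and pooled by presynaptic
    e/i identity.  Undefined ratios (empty partition) come back as NaN, never
    as 0.  With the final trained profile this can be applied retroactively to
    every stored snapshot.
    """
    W = np.asarray(W_rec, float)
    if mask is None:
        mask = W != 0
    if sign is None:
        raise ValueError("sign vector required to partition e/i classes")
    lab = profile.unit_label
    if len(lab) != W.shape[0]:
        raise ValueError("profile does not cover all units")
    e, i = sign > 0, sign < 0
    out = RatioSummary(epoch=epoch)
    groups = {"ee": (e, e), "ei": (e, i), "ie": (i, e), "ii": (i, i),
              "e_pooled": (e, np.ones_like(e)), "i_pooled": (i, np.ones_like(e))}
    for name, (pre, post) in groups.items():
        wm, am = _pair_ratio(W, mask, pre, post, lab, lab)
        out.within_mean[name] = float(wm)
        out.across_mean[name] = float(am)
        out.ratio[name] = float(am / wm) if wm and np.isfinite(wm) and wm > 0 \
            and np.isfinite(am) else np.nan
    return out


def signed_cross_within_ratio(W_rec: np.ndarray, profile: ModulationProfile,
                              epoch: int | None = None) -> RatioSummary:
    """Ratios pooled by current weight sign (for networks without Dale's law)."""
    W = np.asarray(W_rec, float)
    lab = profile.unit_label
    allu = np.ones(W.shape[0], dtype=bool)
    out = RatioSummary(epoch=epoch)
    for name, m in (("positive", W > 0), ("negative", W < 0)):
        wm, am = _pair_ratio(W, m, allu, allu, lab, lab)
        out.within_mean[name], out.across_mean[name] = float(wm), float(am)
        out.ratio[name] = float(am / wm) if wm and np.isfinite(wm) and wm > 0 \
            and np.isfinite(am) else np.nan
    return out


def input_modulation_ratio(W_in: np.ndarray, channel_label: np.ndarray,
                           sign: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """Mean '1'-modulated over mean '0'-modulated nonzero input weight.

    Computed separately for excitatory and inhibitory targets.  Returns
    ``{"onto_e": r, "onto_i": r}`` with NaN where a channel class is empty.
    """
    W = np.asarray(W_in, float)
    if mask is None:
        mask = W != 0
    channel_label = np.asarray(channel_label)
    res = {}
    for name, tgt in (("onto_e", sign > 0), ("onto_i", sign < 0)):
        means = {}
        for lab in (0, 1):
            sel = mask & (channel_label == lab)[:, None] & tgt[None, :]
            w = np.abs(W[sel])
            means[lab] = w.mean() if w.size else np.nan
        res[name] = float(means[1] / means[0]) if means[0] and np.isfinite(means[0]) \
            and np.isfinite(means[1]) else np.nan
    return res


def top_quantile_persistence(W_init: np.ndarray, W_final: np.ndarray, q: float,
                             mask: np.ndarray | None = None) -> float:
    """Fraction of the initial top-q |weight| connections still in the final top q.

    Quantiles are taken over active connections (the union of connections
    active at either endpoint is not used; each matrix ranks its own active
    set).  Requires at least 1/q active connections.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    Wi, Wf = np.asarray(W_init, float), np.asarray(W_final, float)
    if Wi.shape != Wf.shape:
        raise ValueError("weight matrices must share a shape")
    mi = (Wi != 0) if mask is None else np.asarray(mask, bool)
    mf = (Wf != 0) if mask is None else np.asarray(mask, bool)
    if mi.sum() < 1 / q or mf.sum() < 1 / q:
        raise ValueError(f"fewer than {int(np.ceil(1 / q))} active connections")

    def top_set(W, m):
        idx = np.flatnonzero(m.ravel())
        vals = np.abs(W.ravel()[idx])
        k = max(1, int(round(q * len(idx))))
        return set(idx[np.argsort(vals, kind="stable")[-k:]])

    init_top = top_set(Wi, mi)
    final_top = top_set(Wf, mf)
    return len(init_top & final_top) / len(init_top)


_CLASS_DEFS = ("in_e", "in_i", "ee", "ei", "ie", "ii", "e_out", "i_out")


def weight_summary(ws: WeightSet, profile: ModulationProfile | None = None) -> pd.DataFrame:
    """Mean and SD of nonzero weights per layer/class.

    Rows: in->e, in->i, e->e, e->i, i->e, i->i, e->out, i->out.  With a
    ``profile``, the recurrent classes are additionally split by modulation
    pairing ('0'->'0', '1'->'1', '0'->'1', '1'->'0').
    """
    e, i = ws.e_mask, ws.i_mask
    rows = []

    def add(name, values, pairing=None):
        values = values[values != 0]
        rows.append({"class": name, "pairing": pairing, "n": int(values.size),
                     "mean": float(values.mean()) if values.size else np.nan,
                     "sd": float(values.std()) if values.size else np.nan})

    add("in_e", ws.W_in[:, e].ravel())
    add("in_i", ws.W_in[:, i].ravel())
    blocks = {"ee": (e, e), "ei": (e, i), "ie": (i, e), "ii": (i, i)}
    for name, (pre, post) in blocks.items():
        add(name, ws.W_rec[np.ix_(pre, post)].ravel())
        if profile is not None:
            lab = profile.unit_label
            for lp, lq in ((0, 0), (1, 1), (0, 1), (1, 0)):
                sel = (pre & (lab == lp))[:, None] & (post & (lab == lq))[None, :]
                add(name, ws.W_rec[sel].ravel(), pairing=f"{lp}->{lq}")
    add("e_out", ws.W_out[e].ravel())
    add("i_out", ws.W_out[i].ravel())
    return pd.DataFrame(rows)


def ks_compare(sample_a, sample_b):
    """Two-sample Kolmogorov-Smirnov test: returns (D, p)."""
    a, b = np.asarray(sample_a).ravel(), np.asarray(sample_b).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ratio_trajectory(snapshots, profile: ModulationProfile,
                     sign: np.ndarray) -> pd.DataFrame:
    """Retroactive cross/within ratios over stored weight snapshots.

    ``snapshots`` is a list of ``(update_index, WeightSet)``; the final
    profile is applied to every epoch, as the reference analysis tracks
    modulation retroactively.
    """
    frames = []
    for upd, ws in snapshots:
        rs = cross_within_ratio(ws.W_rec, profile, mask=ws.mask_rec,
                                sign=sign, epoch=upd)
        frames.append(rs.to_frame())
    return pd.concat(frames, ignore_index=True)
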