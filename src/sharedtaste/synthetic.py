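"""Synthetic rating data with a known crossed variance-component structure.

The generator emulates the study design — 62 raters x 22 singers x 3
melodies x 5 vocalization styles (330 stimuli) x 2 sessions — under the
Gaussian crossed model

    y_{rit} = mu_style(i) + a_r + b_i + c_t + d_{ri} + e_{rt} + eps_{rit}

where every term is an independent zero-mean Gaussian with its configured
variance: rater bias a, stimulus (shared-taste) effect b, session effect
c, rater x stimulus (private-taste) effect d, rater x session effect e,
and residual noise eps.  The stimulus effect is split into a
style-invariant singer-quality part and a style-specific part,

    b_i = q_singer(i) * sqrt(rho_q) * sigma_item + b'_i * sqrt(1 - rho_q) * sigma_item,

so that the consistency of average singer preferences *across* styles
(interstyle agreement) can be tuned via ``singer_quality_share`` (rho_q)
without touching the rater-side components.  Ratings are optionally
discretized to the 1-9 Likert scale by rounding and clipping.

Default parameters emulate the published study's summary statistics (see
docs/methods.md): style means between 3.8 and 5.4 Likert points, a
per-style MM1 around 0.5, bi1 ~ 0.6, bi2 ~ 0.8, test-retest reliability
~ 0.5 and interstyle agreement ~ 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rating_data import STYLES, RatingTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate_ratings", "sweep_shared_taste"]

#: Default per-style grand means (Likert points), matching the ordering
#: infant-directed < opera < adult-directed < lullaby < pop.
DEFAULT_MU = {"lullaby": 5.20, "pop": 5.42, "opera": 4.51, "AD": 4.83, "ID": 3.81}


def _per_style(value, styles) -> dict:
    """Broadcast a scalar (or validate a mapping) to a per-style dict."""
    if isinstance(value, dict):
        missing = set(styles) - set(value)
        if missing:
            raise ValueError(f"missing styles in per-style mapping: {sorted(missing)}")
        return {s: float(value[s]) for s in styles}
    return {s: float(value) for s in styles}


@dataclass
class SyntheticConfig:
    """Design dimensions and ground-truth variance components.

    Variances are in squared Likert points.  ``mu_style``, ``sigma2_item``,
    ``sigma2_rater_item`` and ``sigma2_res`` accept either a scalar or a
    per-style mapping; the rater- and session-side components are global
    scalars (the crossed design shares raters and sessions across styles).
    """

    n_raters: int = 62
    n_singers: int = 22
    n_melodies: int = 3
    styles: tuple = STYLES
    n_sessions: int = 2
    mu_style: float | dict = field(default_factory=lambda: dict(DEFAULT_MU))
    sigma2_item: float | dict = 0.7
    sigma2_rater: float = 1.6
    sigma2_rater_item: float | dict = 1.1
    sigma2_time: float = 0.02
    sigma2_rater_time: float = 0.25
    sigma2_res: float | dict = 1.8
    discretize: bool = True
    singer_quality_share: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for dim, name in [
            (self.n_raters, "n_raters"),
            (self.n_singers, "n_singers"),
            (self.n_melodies, "n_melodies"),
            (self.n_sessions, "n_sessions"),
        ]:
            if dim < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.singer_quality_share <= 1:
            raise ValueError("singer_quality_share must be in [0, 1]")
        for name in ("sigma2_rater", "sigma2_time", "sigma2_rater_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma2_item", "sigma2_rater_item", "sigma2_res"):
            val = getattr(self, name)
            vals = val.values() if isinstance(val, dict) else [val]
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_items(self) -> int:
        return self.n_singers * self.n_melodies * len(self.styles)

    @property
    def items_per_style(self) -> int:
        return self.n_singers * self.n_melodies

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load a config from a YAML or JSON file mirroring the field names."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if "styles" in data:
            data["styles"] = tuple(data["styles"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Realized effects and implied population quantities of one draw."""

    singer_quality: np.ndarray  # (n_singers,)
    item_effects: np.ndarray  # (n_items,) total b_i
    rater_effects: np.ndarray  # (n_raters,)
    session_effects: np.ndarray  # (n_sessions,)
    rater_item_effects: np.ndarray  # (n_raters, n_items)
    rater_session_effects: np.ndarray  # (n_raters, n_sessions)
    implied_bi1: dict  # per style
    implied_bi2: dict
    implied_mm1: dict  # asymptotic per-rater correlation, per style


def generate_ratings(config: SyntheticConfig) -> tuple[RatingTable, GroundTruth]:
    """Draw one rating dataset under the configured crossed Gaussian model.

    The RNG stream is partitioned by cluster (independent child seeds per
    effect), in item-side-first order, so that enlarging the rater panel
    leaves the item effects — and existing raters' private-taste effects —
    unchanged.  Bitwise reproducible for a fixed config and seed.
    """
    cfg = config
    styles = list(cfg.styles)
    n_i = cfg.n_items
    mu = _per_style(cfg.mu_style, styles)
    s2_item = _per_style(cfg.sigma2_item, styles)
    s2_ri = _per_style(cfg.sigma2_rater_item, styles)
    s2_res = _per_style(cfg.sigma2_res, styles)
    rho = cfg.singer_quality_share

    # stimulus catalogue: style-major, then singer, then melody
    meta_rows = []
    for style in styles:
        for s in range(cfg.n_singers):
            for m in range(cfg.n_melodies):
                meta_rows.append(
                    {
                        "stimulus_id": f"{style}_s{s + 1:02d}_m{m + 1}",
                        "singer_id": f"s{s + 1:02d}",
                        "melody_id": f"m{m + 1}",
                        "style": style,
                    }
                )
    meta = pd.DataFrame(meta_rows)
    item_style = meta["style"].to_numpy()
    item_singer_idx = np.repeat(
        np.tile(np.arange(cfg.n_singers), len(styles)), cfg.n_melodies
    )

    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    rng_q, rng_b, rng_a, rng_c, rng_d, rng_e, rng_eps = (
        np.random.default_rng(s) for s in streams
    )

    sd_item = np.array([np.sqrt(s2_item[st]) for st in item_style])
    q = rng_q.standard_normal(cfg.n_singers)
    b_specific = rng_b.standard_normal(n_i)
    b = (
        q[item_singer_idx] * np.sqrt(rho) * sd_item
        + b_specific * np.sqrt(1.0 - rho) * sd_item
    )
    a = rng_a.standard_normal(cfg.n_raters) * np.sqrt(cfg.sigma2_rater)
    c = rng_c.standard_normal(cfg.n_sessions) * np.sqrt(cfg.sigma2_time)
    sd_ri = np.array([np.sqrt(s2_ri[st]) for st in item_style])
    d = rng_d.standard_normal((cfg.n_raters, n_i)) * sd_ri[None, :]
    e = rng_e.standard_normal((cfg.n_raters, cfg.n_sessions)) * np.sqrt(
        cfg.sigma2_rater_time
    )
    sd_eps = np.array([np.sqrt(s2_res[st]) for st in item_style])
    eps = (
        rng_eps.standard_normal((cfg.n_raters, n_i, cfg.n_sessions))
        * sd_eps[None, :, None]
    )

    mu_items = np.array([mu[st] for st in item_style])
    y = (
        mu_items[None, :, None]
        + a[:, None, None]
        + b[None, :, None]
        + c[None, None, :]
        + d[:, :, None]
        + e[:, None, :]
        + eps
    )
    if cfg.discretize:
        y = np.clip(np.rint(y), 1, 9).astype(int)

    rater_ids = [f"r{j + 1:03d}" for j in range(cfg.n_raters)]
    records = pd.DataFrame(
        {
            "rater_id": np.repeat(rater_ids, n_i * cfg.n_sessions),
            "stimulus_id": np.tile(
                np.repeat(meta["stimulus_id"].to_numpy(), cfg.n_sessions),
                cfg.n_raters,
            ),
            "session": np.tile(
                np.arange(1, cfg.n_sessions + 1), cfg.n_raters * n_i
            ),
            "rating": y.reshape(-1),
        }
    )
    table = RatingTable(records, meta)

    implied_bi1, implied_bi2, implied_mm1 = {}, {}, {}
    for st in styles:
        si, sri, sres = s2_item[st], s2_ri[st], s2_res[st]
        taste = si + sri
        implied_bi1[st] = sri / taste if taste > 0 else np.nan
        denom2 = si + cfg.sigma2_rater + sri
        implied_bi2[st] = (
            (cfg.sigma2_rater + sri) / denom2 if denom2 > 0 else np.nan
        )
        stable = si + sri + sres / cfg.n_sessions
        implied_mm1[st] = np.sqrt(si / stable) if stable > 0 and si > 0 else 0.0

    truth = GroundTruth(
        singer_quality=q,
        item_effects=b,
        rater_effects=a,
        session_effects=c,
        rater_item_effects=d,
        rater_session_effects=e,
        implied_bi1=implied_bi1,
        implied_bi2=implied_bi2,
        implied_mm1=implied_mm1,
    )
    return table, truth


def sweep_shared_taste(
    base: SyntheticConfig,
    shared_fractions,
    replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep the shared fraction of taste variance; summarize MM1 and bi1.

    The total taste variance sigma2_item + sigma2_rater_item of ``base``
    is held fixed while its shared share f = sigma2_item / total runs over
    ``shared_fractions``.  For each (fraction, replicate) a fresh dataset
    is generated and scored: MM1 on the session-averaged full matrix and
    bi1 from the variance components of the first style slice.  Returns a
    tidy DataFrame with one row per fraction x replicate.
    """
    from .agreement import mm1
    from .rating_data import average_sessions
    from .varcomp import beholder_indices, estimate_variance_components

    if not isinstance(base.sigma2_item, (int, float)) or not isinstance(
        base.sigma2_rater_item, (int, float)
    ):
        raise ValueError("sweep requires scalar taste variances in the base config")
    total = float(base.sigma2_item) + float(base.sigma2_rater_item)
    fractions = [float(f) for f in shared_fractions]
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("shared fractions must lie in [0, 1]")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(fractions) * replicates
    )
    rows = []
    k = 0
    cfg_dict = asdict(base)
    for frac in fractions:
        for rep in range(replicates):
            cfg_dict.update(
                sigma2_item=frac * total,
                sigma2_rater_item=(1 - frac) * total,
                seed=int(child_seeds[k] % (2**31)),
            )
            cfg_dict["styles"] = tuple(cfg_dict["styles"])
            cfg = SyntheticConfig(**cfg_dict)
            table, _ = generate_ratings(cfg)
            matrix = average_sessions(table)
            mm1_val = mm1(matrix).estimate
            style0 = cfg.styles[0]
            vc = estimate_variance_components(table.subset_style(style0))
            try:
                bi1 = beholder_indices(vc).bi1
            except ZeroDivisionError:
                bi1 = np.nan
            rows.append(
                {"fraction": frac, "replicate": rep, "mm1": mm1_val, "bi1": bi1}
            )
            k += 1
    return pd.DataFrame(rows)
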