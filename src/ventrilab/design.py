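"""Trial-sequence generation for the LT and ST recalibration paradigms.

Both paradigms present audiovisual (AV) trials in which the visual stimulus
is displaced from the sound by one of six discrepancies (ΔVA), each AV trial
immediately followed by an auditory-only (A) trial, with occasional visual
(V) catch trials inserted after A trials.  The long-term (LT) session holds
the sign of ΔVA constant within each block (three leftward blocks, then
three rightward); the short-term (ST) session interleaves all six ΔVA
within every block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The five speaker azimuths in degrees (negative = left of midline).
SPEAKER_POSITIONS = np.round(np.arange(-2, 3) * 11.6, 1)

#: The six audiovisual discrepancies (visual minus auditory position).
DVA_LEVELS = np.round(np.array([-3, -2, -1, 1, 2, 3]) * 11.6, 1)

# Everything internal works on an integer grid in units of the 11.6° speaker
# spacing; degrees are produced only at the edge (avoids float-set membership).
_SPEAKER_UNITS = np.arange(-2, 3)
_DVA_UNITS = np.array([-3, -2, -1, 1, 2, 3])

#: trial counts per paradigm: (AV, A, V)
TRIAL_COUNTS = {"LT": (432, 432, 72), "ST": (360, 360, 55)}

#: number of blocks per paradigm
N_BLOCKS = {"LT": 6, "ST": 5}

COLUMNS = [
    "paradigm",
    "block",
    "trial_index",
    "trial_type",
    "a_loc",
    "v_loc",
    "delta_va",
    "response",
    "prev_av_index",
]


def _deg(units: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(units, dtype=float) * 11.6, 1)


def _block_dva_pool(paradigm: str, block: int) -> np.ndarray:
    """Balanced pool of ΔVA units for one block.

    LT: blocks 1-3 use the three negative ΔVA (24 repeats each), blocks 4-6
    the three positive ones; ST: every block carries all six ΔVA, 12 repeats
    each.  This yields 72 repeats per ΔVA in LT and 60 in ST.
    """
    if paradigm == "LT":
        levels = _DVA_UNITS[_DVA_UNITS < 0] if block <= 3 else _DVA_UNITS[_DVA_UNITS > 0]
        return np.repeat(levels, 24)
    return np.repeat(_DVA_UNITS, 12)


def _sample_a_loc(dva_units: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample an auditory position uniformly among those compatible with ΔVA.

    A position is compatible when the implied visual position a + ΔVA is one
    of the five speakers; this reproduces the stated ΔVA marginals while
    drawing the stimulus pair "semi-independently".
    """
    a = np.empty(dva_units.shape, dtype=int)
    for d in np.unique(dva_units):
        valid = _SPEAKER_UNITS[np.isin(_SPEAKER_UNITS + d, _SPEAKER_UNITS)]
        sel = dva_units == d
        a[sel] = valid[rng.integers(0, valid.size, size=int(sel.sum()))]
    return a


def generate_design(paradigm: str, seed: int) -> pd.DataFrame:
    """Generate one session's trial table.

    Parameters
    ----------
    paradigm:
        ``"LT"`` or ``"ST"``.
    seed:
        Seed for the pseudorandomized trial ordering; identical seeds give
        byte-identical tables.

    Returns
    -------
    DataFrame with one row per trial (columns :data:`COLUMNS`).  AV trials
    carry ``a_loc``, ``v_loc`` and ``delta_va``; each is immediately followed
    by an A trial whose ``prev_av_index`` points back at it; V trials are
    inserted after A trials.  ``response`` is NaN until behavior is simulated.
    """
    if paradigm not in TRIAL_COUNTS:
        raise ValueError(f"unknown paradigm {paradigm!r}; expected 'LT' or 'ST'")
    rng = np.random.default_rng(seed)
    n_av, _, n_v = TRIAL_COUNTS[paradigm]
    n_blocks = N_BLOCKS[paradigm]
    av_per_block = n_av // n_blocks
    # V trials per block; ST has 55 = 11 * 5
    v_per_block = np.full(n_blocks, n_v // n_blocks)
    v_per_block[: n_v % n_blocks] += 1

    rows: list[tuple] = []
    idx = 0
    for block in range(1, n_blocks + 1):
        dva = rng.permutation(_block_dva_pool(paradigm, block))
        assert dva.size == av_per_block
        a_units = _sample_a_loc(dva, rng)
        v_units = a_units + dva
        a_only_units = rng.integers(-2, 3, size=av_per_block)
        # positions (among the block's AV–A pairs) after which a V trial goes
        v_slots = set(rng.choice(av_per_block, size=v_per_block[block - 1], replace=False))
        v_locs = rng.integers(-2, 3, size=av_per_block)
        a_deg, v_deg, dva_deg = _deg(a_units), _deg(v_units), _deg(dva)
        a_only_deg, v_only_deg = _deg(a_only_units), _deg(v_locs)
        for k in range(av_per_block):
            av_idx = idx
            rows.append((paradigm, block, av_idx, "AV",
                         a_deg[k], v_deg[k], dva_deg[k], np.nan, -1))
            idx += 1
            rows.append((paradigm, block, idx, "A",
                         a_only_deg[k], np.nan, np.nan, np.nan, av_idx))
            idx += 1
            if k in v_slots:
                rows.append((paradigm, block, idx, "V",
                             np.nan, v_only_deg[k], np.nan, np.nan, -1))
                idx += 1

    df = pd.DataFrame(rows, columns=COLUMNS)
    df["prev_av_index"] = df["prev_av_index"].astype(int)
    return df


def validate_design(df: pd.DataFrame) -> None:
    """Assert the structural invariants of a trial table (raises AssertionError)."""
    paradigm = df["paradigm"].iloc[0]
    n_av, n_a, n_v = TRIAL_COUNTS[paradigm]
    counts = df["trial_type"].value_counts()
    assert counts.get("AV", 0) == n_av and counts.get("A", 0) == n_a
    assert counts.get("V", 0) == n_v
    av = df[df.trial_type == "AV"]
    assert not np.any(np.isclose(av.delta_va, 0.0))
    # AV -> A adjacency
    pos = df.reset_index(drop=True)
    for i in pos.index[pos.trial_type == "A"]:
        assert pos.loc[i - 1, "trial_type"] == "AV"
        assert pos.loc[i, "prev_av_index"] == pos.loc[i - 1, "trial_index"]
    for i in pos.index[pos.trial_type == "V"]:
        assert pos.loc[i - 1, "trial_type"] == "A"
    if paradigm == "LT":
        for b, sub in av.groupby("block"):
            sign = -1 if b <= 3 else 1
            assert np.all(np.sign(sub.delta_va) == sign)
    else:
        for _, sub in av.groupby("block"):
            assert (sub.delta_va < 0).any() and (sub.delta_va > 0).any()
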