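"""Named, counter-based random-number streams.

Every source of randomness in the package draws from one of a small set of
named roles.  Streams for different roles (or different substream indices
within a role) are statistically independent and individually reproducible:
regenerating the stimuli of an experiment never perturbs the internal-noise
draws, and vice versa.
"""

from __future__ import annotations

import numpy as np

#: role name -> fixed stream id (order is part of the reproducibility contract)
ROLES = {
    "stimulus": 0,
    "internal": 1,
    "connectivity": 2,
    "init": 3,
    "external": 4,
    "bootstrap": 5,
    "fit": 6,
}


def rng_for(seed: int, role: str, index: int = 0) -> np.random.Generator:
    """Return the generator for a (seed, role, substream-index) triple.

    Parameters
    ----------
    seed
        Experiment master seed (non-negative integer).
    role
        One of ``ROLES`` (e.g. ``"stimulus"``, ``"internal"``).
    index
        Substream counter within the role, for e.g. per-cell streams in a
        parameter sweep.
    """
    if role not in ROLES:
        raise ValueError(f"unknown RNG role {role!r}; valid roles: {sorted(ROLES)}")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(ROLES[role], int(index)))
    return np.random.default_rng(ss)
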