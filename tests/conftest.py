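"""Shared fixtures: deterministic toy targets and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from repairscape.indel_core import TargetSite

PROTO_START = 13
PAM_START = 33
CUT = PAM_START - 3


def make_site(
    site_id: str = "site",
    distal: str = "T",
    proximal: str = "G",
    seed: int = 0,
    length: int = 79,
) -> TargetSite:
    """Random NGG target with chosen cut-flanking bases, deterministic per seed."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    seq[PAM_START + 1] = "G"
    seq[PAM_START + 2] = "G"
    seq[CUT - 1] = distal
    seq[CUT] = proximal
    return TargetSite(site_id, "".join(seq), PROTO_START, PAM_START)


@pytest.fixture(scope="session")
def site() -> TargetSite:
    return make_site()


@pytest.fixture(scope="session")
def homopolymer_site() -> TargetSite:
    """All-G target: maximal representation ambiguity for every edit."""
    return TargetSite("homopolymer", "G" * 79, PROTO_START, PAM_START)


@pytest.fixture(scope="session")
def repeat_free_site() -> TargetSite:
    """Target on which no in-window deletion has an equivalent representation.

    Right of the cut a single letter (G, also supplying the PAM) and left of
    it a different single letter, with distinct bases at the two
    cut-adjacent positions, guarantee that every deletion window differs
    from its neighbours, so all 495 candidate deletions are distinct.
    """
    seq = "C" * 29 + "T" + "A" + "G" * 49
    return TargetSite("repeat_free", seq, PROTO_START, PAM_START)


@pytest.fixture(scope="session")
def library16():
    from repairscape.synthetic_data import make_library

    return make_library(16, seed=42)
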