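"""Common-random-number stream management.

Layout comparisons in the factorial experiments use common random numbers
(CRN): replication j of every layout must consume *identical* randomness
for arrival realization, service-time draws and deferral draws, so that
the paired difference between two layouts reflects the layout and not the
noise. Keying streams by (replication, donor-id, activity) — rather than
drawing from one sequential stream — makes the pairing exact even when a
layout change reorders events: donor ``d2-b03``'s phlebotomy duration is
the same number in every layout of the same replication.

Implementation: each key is hashed (CRC32, stable across processes) into a
``numpy`` ``SeedSequence`` spawn key under the master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["StreamFamily"]


def _key32(text: str) -> int:
    return zlib.crc32(text.encode("utf-8")) & 0xFFFFFFFF


@dataclass(frozen=True)
class StreamFamily:
    """Factory of independent, reproducibly keyed random generators.

    Parameters
    ----------
    master_seed
        Seed shared by the whole experiment plan.
    replication
        Replication index; streams differ across replications but are
        identical across layouts within one replication.
    """

    master_seed: int
    replication: int = 0

    def stream(self, donor_id: str, activity: str) -> np.random.Generator:
        """Generator for one (donor, activity) pair, independent of layout."""
        ss = np.random.SeedSequence(
            entropy=self.master_seed,
            spawn_key=(self.replication, _key32(donor_id), _key32(activity)),
        )
        return np.random.Generator(np.random.PCG64(ss))

    def named(self, purpose: str) -> np.random.Generator:
        """Generator for a non-donor purpose (e.g. schedule synthesis)."""
        return self.stream("_global_", purpose)
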