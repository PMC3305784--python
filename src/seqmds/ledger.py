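"""Exact operation counting for complexity verification.

The interpolative pipeline's value proposition is a cost reduction from
O(N^2) pairwise alignments to O(M^2 + (N-M)*M).  Rather than benchmark
wall-clock time (hardware-dependent), every alignment and every
majorization sweep increments a :class:`CostLedger`, so the complexity
contract can be asserted as exact integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class CostLedger:
    """Monotonically nondecreasing counters of the expensive primitives.

    Attributes
    ----------
    nw_alignments:
        Number of Needleman-Wunsch alignments executed.
    smacof_iterations:
        Guttman-transform sweeps performed by full MDS.
    majorization_iterations:
        Per-point majorization iterations performed during interpolation,
        summed over all interpolated points.
    """

    nw_alignments: int = 0
    smacof_iterations: int = 0
    majorization_iterations: int = 0

    def add_alignments(self, n: int) -> None:
        if n < 0:
            raise ValueError("alignment count increment must be nonnegative")
        self.nw_alignments += n

    def add_smacof_iterations(self, n: int) -> None:
        if n < 0:
            raise ValueError("iteration count increment must be nonnegative")
        self.smacof_iterations += n

    def add_majorization_iterations(self, n: int) -> None:
        if n < 0:
            raise ValueError("iteration count increment must be nonnegative")
        self.majorization_iterations += n

    def as_dict(self) -> dict:
        return {
            "nw_alignments": self.nw_alignments,
            "smacof_iterations": self.smacof_iterations,
            "majorization_iterations": self.majorization_iterations,
        }
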