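"""Takahashi–Tango extended power: detection weights, EP curves, AUC_EP.

For a true cluster of ``s`` SUs, each significant detection of size ``l``
with ``s*`` true positives is weighted by

    W(l, s*, w+, w-) = (1 - min(w- (s - s*), 1)) (1 - min(w+ (l - s*), 1))

with the false-negative penalty fixed at ``w- = 1/s`` and the false-positive
penalty expressed through the ratio ``q = w+ / w-`` (so ``w+ = q / s``):

    W(l, s*, q) = (s*/s) * max(0, 1 - q (l - s*) / s).

Extended power at a given q is the weighted proportion of eligible detected
clusters (size l <= L) over all submitted datasets; non-rejections and
oversize detections contribute zero but stay in the denominator.  AUC_EP
integrates the EP curve over q in [0, 1] — 0 marks an inoperative test
(never a true positive), 1 a perfect one (always rejected, always exactly
the true cluster).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .region import Cluster
from .scan import ScanResults

__all__ = [
    "DetectionTally",
    "EPCurve",
    "classify_detection",
    "weight",
    "extended_power",
    "auc_ep",
    "ep_curve",
]

NOT_REJECTED = "not_rejected"
OVERSIZE = "oversize"


@dataclass
class DetectionTally:
    """Detection record of one (cluster, scenario) cell of the experiment.

    ``counts`` maps (l, s*) — detected size and true-positive count — to the
    number of datasets producing that detection; datasets where H0 was not
    rejected or whose detection exceeded the size cap L are tracked
    separately and count toward the denominator only.
    """

    true_cluster_size: int
    max_size: int
    n_datasets: int = 0
    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    n_not_rejected: int = 0
    n_oversize: int = 0

    def validate(self) -> None:
        s, L = self.true_cluster_size, self.max_size
        if s < 1 or L < 1:
            raise ValueError("true_cluster_size and max_size must be >= 1")
        total = self.n_not_rejected + self.n_oversize
        for (l, s_star), c in self.counts.items():
            if c < 0:
                raise ValueError("counts must be >= 0")
            if not (1 <= l <= L):
                raise ValueError(f"detected size l={l} outside 1..L={L}")
            if not (0 <= s_star <= min(l, s)):
                raise ValueError(f"s*={s_star} outside 0..min(l={l}, s={s})")
            total += c
        if total != self.n_datasets:
            raise ValueError(
                f"tally does not add up: {total} events for {self.n_datasets} datasets"
            )

    def add(self, event) -> None:
        """Record one dataset's outcome: NOT_REJECTED, OVERSIZE or (l, s*)."""
        self.n_datasets += 1
        if event == NOT_REJECTED:
            self.n_not_rejected += 1
        elif event == OVERSIZE:
            self.n_oversize += 1
        else:
            l, s_star = event
            self.counts[(int(l), int(s_star))] = self.counts.get((int(l), int(s_star)), 0) + 1

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["# s", self.true_cluster_size])
            w.writerow(["# L", self.max_size])
            w.writerow(["# n_datasets", self.n_datasets])
            w.writerow(["# n_not_rejected", self.n_not_rejected])
            w.writerow(["# n_oversize", self.n_oversize])
            w.writerow(["l", "s_star", "count"])
            for (l, s_star), c in sorted(self.counts.items()):
                w.writerow([l, s_star, c])

    @classmethod
    def from_csv(cls, path) -> "DetectionTally":
        meta: dict[str, int] = {}
        counts: dict[tuple[int, int], int] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row:
                    continue
                if row[0].startswith("#"):
                    meta[row[0].lstrip("# ")] = int(row[1])
                elif row[0] != "l":
                    counts[(int(row[0]), int(row[1]))] = int(row[2])
        tally = cls(
            true_cluster_size=meta["s"],
            max_size=meta["L"],
            n_datasets=meta["n_datasets"],
            counts=counts,
            n_not_rejected=meta["n_not_rejected"],
            n_oversize=meta["n_oversize"],
        )
        tally.validate()
        return tally


@dataclass(frozen=True)
class EPCurve:
    """Extended power evaluated on a q grid, with intercept and AUC."""

    q_grid: np.ndarray
    ep_values: np.ndarray
    intercept: float
    auc: float


def classify_detection(
    scan_result: ScanResults, true_cluster: Cluster, L: int
) -> str | tuple[int, int]:
    """Outcome of one dataset: NOT_REJECTED, OVERSIZE, or (l, s*)."""
    if not scan_result.significant:
        return NOT_REJECTED
    l = scan_result.mlc_size
    if l > L:
        return OVERSIZE
    s_star = len(scan_result.mlc_members & true_cluster.members)
    return (l, s_star)


def weight(l: int, s_star: int, s: int, q: float) -> float:
    """Detection weight W(l, s*, q) in [0, 1]."""
    if s < 1:
        raise ValueError("s must be >= 1")
    if not 0 <= s_star <= min(l, s):
        raise ValueError(f"need 0 <= s* <= min(l, s); got l={l}, s*={s_star}, s={s}")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return (s_star / s) * max(0.0, 1.0 - q * (l - s_star) / s)


def extended_power(tally: DetectionTally, q: float) -> float:
    """EP(q): weighted proportion of eligible detections among all datasets."""
    tally.validate()
    if tally.n_datasets == 0:
        raise ValueError("tally has no datasets")
    s = tally.true_cluster_size
    total = sum(
        weight(l, s_star, s, q) * c for (l, s_star), c in tally.counts.items()
    )
    return total / tally.n_datasets


def _cell_auc(l: int, s_star: int, s: int) -> float:
    """Closed-form integral of W(l, s*, q) over q in [0, 1].

    With a = (l - s*)/s the weight is (s*/s) max(0, 1 - a q), so the
    integral is (s*/s)(1 - a/2) while the weight stays positive on [0, 1]
    (a <= 1), and (s*/s)/(2a) when it hits zero inside (a > 1).
    """
    a = (l - s_star) / s
    frac = s_star / s
    if a <= 1.0:
        return frac * (1.0 - a / 2.0)
    return frac / (2.0 * a)


def auc_ep(tally: DetectionTally) -> float:
    """Area under the EP curve for q in [0, 1], computed in closed form."""
    tally.validate()
    if tally.n_datasets == 0:
        raise ValueError("tally has no datasets")
    s = tally.true_cluster_size
    total = sum(_cell_auc(l, s_star, s) * c for (l, s_star), c in tally.counts.items())
    return total / tally.n_datasets


def ep_curve(tally: DetectionTally, q_step: float = 0.01) -> EPCurve:
    """EP evaluated on the grid 0, q_step, ..., 1 plus intercept and AUC.

    The grid is for reporting only; the intercept is EP(0) and the AUC comes
    from the exact per-cell integrals, independent of q_step.
    """
    if not 0.0 < q_step <= 1.0:
        raise ValueError("q_step must be in (0, 1]")
    n_steps = int(round(1.0 / q_step))
    q_grid = np.linspace(0.0, 1.0, n_steps + 1)
    ep_values = np.array([extended_power(tally, q) for q in q_grid])
    return EPCurve(
        q_grid=q_grid,
        ep_values=ep_values,
        intercept=float(ep_values[0]),
        auc=auc_ep(tally),
    )


def export_ep_curve(curve: EPCurve, path) -> None:
    """Write the (q, EP) grid as a two-column CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["q", "EP"])
        for q, ep in zip(curve.q_grid, curve.ep_values):
            w.writerow([repr(float(q)), repr(float(ep))])
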