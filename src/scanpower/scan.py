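"""Kulldorff's circular purely-spatial Poisson scan statistic.

Candidate zones are circles: each SU centroid in turn is a circle center,
and growing the radius adds SUs in order of increasing centroid distance,
up to a population cap (and optionally an SU-count cap).  For a zone *z*
with ``n_z`` cases and at-risk population ``N_z`` (region totals ``n``,
``N``), the log likelihood-ratio statistic is

    LLR(z) = n_z ln(n_z / (lam N_z)) + (n - n_z) ln((n - n_z) / (lam (N - N_z)))

when ``n_z > lam N_z`` and 0 otherwise, with the convention 0 ln 0 = 0.
``lam`` is the global incidence, by default estimated as ``n / N`` from the
dataset (a fixed design value may be supplied instead).  The zone
maximizing LLR is the most likely cluster (MLC); its significance is
assessed by Monte Carlo, ranking the observed maximum among maxima of null
replicates.

The model/results pair follows the usual estimator idiom:

>>> scan = KulldorffScan(dataset)           # doctest: +SKIP
>>> res = scan.fit(mc_replicates=999, seed=7)
>>> res.p_value, sorted(res.mlc_members)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .region import Region
from .simulate import CaseDataset

try:  # jit kernel for the Monte Carlo hot loop; numpy fallback stays exact
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "Zone",
    "ZoneSystem",
    "enumerate_zones",
    "log_likelihood_ratio",
    "find_most_likely_cluster",
    "monte_carlo_p_value",
    "KulldorffScan",
    "ScanResults",
]


@dataclass(frozen=True)
class Zone:
    """One circular candidate zone: members ordered by distance from center."""

    center_su: str
    members: tuple[str, ...]
    population: float

    @property
    def n_members(self) -> int:
        return len(self.members)


def log_likelihood_ratio(
    n_z: int, N_z: float, n_total: int, N_total: float, lam: float
) -> float:
    """Scalar Poisson log likelihood ratio for one zone.

    Returns 0 when the zone is not over-incident (``n_z <= lam * N_z``).
    """
    if not 0 <= n_z <= n_total:
        raise ValueError("need 0 <= n_z <= n_total")
    if not 0 < N_z < N_total:
        raise ValueError("need 0 < N_z < N_total")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if n_z <= lam * N_z:
        return 0.0
    inside = n_z * math.log(n_z / (lam * N_z))  # n_z > lam N_z > 0 here
    n_out = n_total - n_z
    outside = 0.0 if n_out == 0 else n_out * math.log(n_out / (lam * (N_total - N_z)))
    return inside + outside


def _llr_array(n_z, N_z, n_total, N_total, lam):
    """Vectorized LLR with the 0 ln 0 convention; shapes broadcast."""
    n_z = np.asarray(n_z, dtype=float)
    N_z = np.asarray(N_z, dtype=float)
    n_out = n_total - n_z
    N_out = N_total - N_z
    with np.errstate(divide="ignore", invalid="ignore"):
        t_in = np.where(n_z > 0, n_z * np.log(n_z / (lam * N_z)), 0.0)
        t_out = np.where(n_out > 0, n_out * np.log(n_out / (lam * N_out)), 0.0)
    llr = np.where(n_z > lam * N_z, t_in + t_out, 0.0)
    return np.where(np.isfinite(llr), llr, 0.0)


def _max_llr_loop(counts, member_idx, lengths, cumpop, log_Nz, log_Nout, logt, totals, lams):
    """Max LLR per replicate row; scalar loop, jitted when numba is present."""
    R = counts.shape[0]
    out = np.zeros(R)
    for r in range(R):
        n = totals[r]
        lam = lams[r]
        log_lam = np.log(lam)
        best = 0.0
        for k in range(member_idx.shape[0]):
            nz = 0
            for j in range(lengths[k]):
                nz += counts[r, member_idx[k, j]]
                if nz > lam * cumpop[k, j]:
                    n_out = n - nz
                    v = nz * (logt[nz] - log_Nz[k, j] - log_lam)
                    if n_out > 0:
                        v += n_out * (logt[n_out] - log_Nout[k, j] - log_lam)
                    if v > best:
                        best = v
        out[r] = best
    return out


if _HAVE_NUMBA:
    _max_llr_loop_jit = _njit(cache=False)(_max_llr_loop)


class ZoneSystem:
    """Precomputed circular-zone structure for a region.

    Zones are nested per center, so the whole system is stored as one padded
    index matrix plus cumulative populations; a full scan is a gather, a
    cumulative sum and one vectorized LLR evaluation.
    """

    def __init__(
        self,
        region: Region,
        max_population_fraction: float = 0.5,
        max_zone_size: int | None = None,
    ) -> None:
        if max_population_fraction <= 0:
            raise ValueError("max_population_fraction must be > 0")
        self.region = region
        self.max_population_fraction = float(max_population_fraction)
        self.max_zone_size = max_zone_size
        n = region.n_units
        cap_pop = self.max_population_fraction * region.total_population
        cap_len = n if max_zone_size is None else min(n, int(max_zone_size))
        lengths = np.zeros(n, dtype=np.int64)
        orders = np.zeros((n, cap_len), dtype=np.int64)  # 0-padded: gathers stay in bounds
        cumpops = np.zeros((n, cap_len), dtype=float)
        tol = 1e-9 * region.total_population
        for k in range(n):
            o = region.neighbor_order(k)[:cap_len]
            cp = np.cumsum(region.populations[o])
            m = int(np.searchsorted(cp, cap_pop + tol, side="right"))
            lengths[k] = m
            orders[k, :m] = o[:m]
            cumpops[k, :m] = cp[:m]
        self.max_len = int(lengths.max())
        self.lengths = lengths
        self.member_idx = orders[:, : self.max_len]
        self.cum_population = cumpops[:, : self.max_len]
        ar = np.arange(self.max_len)
        self.valid = ar[None, :] < lengths[:, None]
        # infinite population on padding keeps the LLR indicator false there
        self.cum_population[~self.valid] = np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            self._log_Nz = np.log(self.cum_population)
            self._log_Nout = np.log(region.total_population - self.cum_population)
        self._logtable = np.log(np.arange(1, 2, dtype=float))  # grown on demand

    @property
    def n_zones(self) -> int:
        return int(self.lengths.sum())

    def zones(self) -> list[Zone]:
        """Materialize the explicit zone list (ordered by center su_id)."""
        ids = self.region.su_ids
        out = []
        for k in range(self.region.n_units):
            for j in range(int(self.lengths[k])):
                mem = tuple(ids[i] for i in self.member_idx[k, : j + 1])
                out.append(Zone(ids[k], mem, float(self.cum_population[k, j])))
        return out

    def _cum_counts(self, counts: np.ndarray) -> np.ndarray:
        """n_z for every zone; counts (..., n) -> (..., n_centers, max_len)."""
        return np.cumsum(counts[..., self.member_idx], axis=-1)

    def _log_int(self, k_max: int) -> np.ndarray:
        """Cached table of ln(k) for integer counts (ln 0 slot unused)."""
        if k_max >= len(self._logtable):
            with np.errstate(divide="ignore"):
                self._logtable = np.log(np.arange(k_max + 1, dtype=float))
        return self._logtable

    def _llr_cum(self, nz: np.ndarray, totals, lam) -> np.ndarray:
        """LLR for cumulative integer counts nz (..., n_centers, max_len).

        Uses ln n_z and ln(n - n_z) from an integer log table and the
        precomputed ln N_z / ln(N - N_z), so no logs are taken per call.
        ``totals`` and ``lam`` broadcast against nz.
        """
        totals = np.asarray(totals)
        lam = np.asarray(lam, dtype=float)
        # padded entries can cumulate beyond the total; size the table by nz
        logt = self._log_int(max(int(totals.max(initial=0)), int(nz.max(initial=0))))
        n_out = totals - nz
        log_lam = np.log(lam)
        with np.errstate(invalid="ignore"):
            t_in = nz * (logt[nz] - self._log_Nz - log_lam)
            t_out = np.where(
                n_out > 0, n_out * (logt[n_out] - self._log_Nout - log_lam), 0.0
            )
            llr = np.where(nz > lam * self.cum_population, t_in + t_out, 0.0)
        return np.where(np.isfinite(llr), llr, 0.0)

    def llr_all(self, counts: np.ndarray, lam: float) -> np.ndarray:
        """LLR of every zone for one counts vector (n_centers, max_len)."""
        counts = np.asarray(counts)
        nz = self._cum_counts(counts.astype(np.int64))
        return self._llr_cum(nz, int(counts.sum()), lam)

    def max_llr_batch(self, counts: np.ndarray, lam: np.ndarray | float) -> np.ndarray:
        """Max LLR per row for a (R, n) batch of counts vectors."""
        counts = np.ascontiguousarray(counts, dtype=np.int64)
        totals = counts.sum(axis=-1)
        lam = np.ascontiguousarray(np.broadcast_to(np.asarray(lam, dtype=float), totals.shape))
        if _HAVE_NUMBA:
            logt = self._log_int(int(totals.max(initial=0)))
            return _max_llr_loop_jit(
                counts, self.member_idx, self.lengths, self.cum_population,
                self._log_Nz, self._log_Nout, logt, totals, lam,
            )
        out = np.empty(counts.shape[0])
        # chunk the replicate axis to bound the (R, n_centers, max_len) gather
        chunk = max(1, int(2_000_000 // max(1, self.region.n_units * self.max_len)))
        for a in range(0, counts.shape[0], chunk):
            b = min(a + chunk, counts.shape[0])
            nz = self._cum_counts(counts[a:b])
            llr = self._llr_cum(nz, totals[a:b, None, None], lam[a:b, None, None])
            out[a:b] = llr.max(axis=(1, 2))
        return out

    def most_likely(self, counts: np.ndarray, lam: float):
        """(member index array, llr, n_z, N_z) of the best zone, with the
        documented tie-break: highest LLR, then fewest members, then lowest
        center su_id."""
        llr = self.llr_all(counts, lam)
        best = llr.max()
        ks, js = np.nonzero(llr >= best - 0.0)  # exact ties only
        pick = np.lexsort((ks, js))[0]  # js = size-1 primary... see below
        # lexsort: last key primary -> sort by zone length, then center rank
        k, j = int(ks[pick]), int(js[pick])
        members = self.member_idx[k, : j + 1]
        nz = int(np.asarray(counts)[members].sum())
        return members, float(llr[k, j]), nz, float(self.cum_population[k, j])


def enumerate_zones(
    region: Region,
    max_population_fraction: float = 0.5,
    max_zone_size: int | None = None,
) -> list[Zone]:
    """All circular zones: nested distance prefixes per center, capped by
    population fraction and optionally by SU count."""
    return ZoneSystem(region, max_population_fraction, max_zone_size).zones()


def _zone_stats(dataset: CaseDataset, zones, su_index) -> tuple[np.ndarray, np.ndarray]:
    n_z = np.array(
        [sum(int(dataset.observed[su_index[m]]) for m in z.members) for z in zones],
        dtype=float,
    )
    N_z = np.array([z.population for z in zones], dtype=float)
    return n_z, N_z


def _resolve_lambda(n_total, N_total, lambda_mode, fixed_lambda) -> float:
    if lambda_mode == "estimated":
        return n_total / N_total
    if lambda_mode == "fixed":
        if fixed_lambda is None or fixed_lambda <= 0:
            raise ValueError("fixed lambda_mode requires fixed_lambda > 0")
        return float(fixed_lambda)
    raise ValueError(f"lambda_mode must be 'estimated' or 'fixed', got {lambda_mode!r}")


def find_most_likely_cluster(
    dataset: CaseDataset,
    zones: list[Zone],
    lambda_mode: str = "estimated",
    fixed_lambda: float | None = None,
) -> tuple[frozenset[str], float]:
    """MLC over an explicit zone list (any list — not necessarily nested).

    Ties (equal LLR) go to the smallest zone, then the lexicographically
    smallest center id.  With no cases at all there is no cluster:
    returns (empty set, 0.0).
    """
    n_total = dataset.n_total
    if n_total == 0:
        return frozenset(), 0.0
    N_total = float(dataset.population.sum())
    lam = _resolve_lambda(n_total, N_total, lambda_mode, fixed_lambda)
    if dataset.su_ids is not None:
        su_index = {sid: i for i, sid in enumerate(dataset.su_ids)}
    else:
        # datasets built from a Region follow its su_id-sorted row order;
        # without explicit ids this only works when every SU is in some zone
        all_ids = sorted({m for z in zones for m in z.members})
        if len(all_ids) != dataset.n_units:
            raise ValueError(
                "dataset carries no su_ids and the zone list does not cover "
                "every SU; cannot align rows with zone members"
            )
        su_index = {sid: i for i, sid in enumerate(all_ids)}
    n_z, N_z = _zone_stats(dataset, zones, su_index)
    llr = _llr_array(n_z, N_z, n_total, N_total, lam)
    full = N_z >= N_total  # whole-region zones never over-incident vs themselves
    llr[full & (n_z <= lam * N_z)] = 0.0
    best = llr.max()
    order = sorted(
        (i for i in range(len(zones)) if llr[i] == best),
        key=lambda i: (zones[i].n_members, zones[i].center_su),
    )
    i = order[0]
    if best == 0.0:
        return frozenset(), 0.0
    return frozenset(zones[i].members), float(best)


@dataclass
class ScanResults:
    """Fitted scan: the most likely cluster and its Monte Carlo inference."""

    mlc_members: frozenset[str]
    mlc_cases: int
    mlc_population: float
    log_lr: float
    p_value: float
    n_mc_replicates: int
    alpha: float
    lam: float
    n_total: int

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    @property
    def mlc_size(self) -> int:
        return len(self.mlc_members)

    def summary(self) -> str:
        lines = [
            "Kulldorff Poisson spatial scan",
            "==============================",
            f"total cases            {self.n_total}",
            f"lambda (global rate)   {self.lam:.6g}",
            f"MLC size (SUs)         {self.mlc_size}",
            f"MLC cases / population {self.mlc_cases} / {self.mlc_population:g}",
            f"log likelihood ratio   {self.log_lr:.4f}",
            f"Monte Carlo p-value    {self.p_value:.4f}  ({self.n_mc_replicates} replicates)",
            f"significant at {self.alpha:g}    {self.significant}",
        ]
        if self.mlc_members:
            lines.append("MLC members: " + ";".join(sorted(self.mlc_members)))
        return "\n".join(lines)


class KulldorffScan:
    """Scan-statistic model for one case dataset.

    Parameters
    ----------
    dataset : CaseDataset
        Rows must follow the region's su_id-sorted SU order (datasets built
        by the simulator do).
    region : Region, optional
        Needed to build the zone system unless ``zones`` is given.
    zones : ZoneSystem, optional
        Reuse a precomputed zone system across many datasets on one region.
    max_population_fraction, max_zone_size
        Scan-window caps used when building the zone system here.
    lambda_mode : {"estimated", "fixed"}
        Global incidence in the LLR: estimated n/N per dataset (default) or
        a fixed design value ``fixed_lambda``.
    null : {"conditional", "poisson"}
        Monte Carlo null: multinomial conditioned on the observed total
        (default) or unconditional Poisson draws from the expected counts.
    """

    def __init__(
        self,
        dataset: CaseDataset,
        region: Region | None = None,
        zones: ZoneSystem | None = None,
        max_population_fraction: float = 0.5,
        max_zone_size: int | None = None,
        lambda_mode: str = "estimated",
        fixed_lambda: float | None = None,
        null: str = "conditional",
    ) -> None:
        if zones is None:
            if region is None:
                raise ValueError("provide either a ZoneSystem or a Region")
            zones = ZoneSystem(region, max_population_fraction, max_zone_size)
        if zones.region.n_units != dataset.n_units:
            raise ValueError("dataset and zone system disagree on the number of SUs")
        if null not in ("conditional", "poisson"):
            raise ValueError("null must be 'conditional' or 'poisson'")
        self.dataset = dataset
        self.zone_system = zones
        self.lambda_mode = lambda_mode
        self.fixed_lambda = fixed_lambda
        self.null = null

    def fit(
        self,
        mc_replicates: int = 999,
        alpha: float = 0.05,
        seed: int | np.random.Generator | None = None,
    ) -> ScanResults:
        if mc_replicates < 1:
            raise ValueError("mc_replicates must be >= 1")
        ds, zs = self.dataset, self.zone_system
        n_total = ds.n_total
        N_total = zs.region.total_population
        if n_total == 0:
            return ScanResults(frozenset(), 0, 0.0, 0.0, 1.0, mc_replicates, alpha, 0.0, 0)
        lam = _resolve_lambda(n_total, N_total, self.lambda_mode, self.fixed_lambda)
        members, llr, nz, Nz = zs.most_likely(ds.observed, lam)
        if llr == 0.0:
            members, nz, Nz = np.array([], dtype=int), 0, 0.0
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        reps = self._null_replicates(rng, mc_replicates)
        if self.lambda_mode == "estimated":
            rep_lam = reps.sum(axis=1) / N_total
        else:
            rep_lam = np.full(mc_replicates, lam)
        rep_max = zs.max_llr_batch(reps, rep_lam)
        p = (1 + int(np.sum(rep_max >= llr))) / (mc_replicates + 1)
        ids = zs.region.su_ids
        return ScanResults(
            mlc_members=frozenset(ids[i] for i in members),
            mlc_cases=int(nz),
            mlc_population=float(Nz),
            log_lr=float(llr),
            p_value=p,
            n_mc_replicates=mc_replicates,
            alpha=alpha,
            lam=lam,
            n_total=n_total,
        )

    def _null_replicates(self, rng: np.random.Generator, R: int) -> np.ndarray:
        eps = self.dataset.expected
        total_eps = eps.sum()
        if self.null == "poisson":
            return rng.poisson(eps, size=(R, len(eps)))
        if total_eps <= 0:
            raise ValueError("cannot draw conditional replicates: all expected counts zero")
        return rng.multinomial(self.dataset.n_total, eps / total_eps, size=R)


def monte_carlo_p_value(
    dataset: CaseDataset,
    zones: ZoneSystem,
    n_replicates: int = 999,
    rng: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    lambda_mode: str = "estimated",
    fixed_lambda: float | None = None,
) -> ScanResults:
    """Functional wrapper: scan ``dataset`` and rank it among conditional
    null replicates."""
    model = KulldorffScan(
        dataset, zones=zones, lambda_mode=lambda_mode, fixed_lambda=fixed_lambda
    )
    return model.fit(mc_replicates=n_replicates, alpha=alpha, seed=rng)
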