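"""Synthetic lips and SSR genotype datasets with known ground truth.

No raw genotype matrix or flower images are publicly deposited for the
*H. radiata* populations this package targets, so every downstream stage is
validated on synthetic inputs that carry the statistical and geometric
structure the analyses assume: parametric "egret" lip contours with
controllable body/wing dimensions, body–wing angle and serration count, and
diploid SSR genotypes with per-population allele-frequency spectra,
within-population inbreeding (F_IS), admixture, or clonal propagation.

All generators are driven by one root seed with deterministically derived
per-component child streams, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .datasets import MISSING, GenotypeDataset
from .morphometrics import Contour, GeometryError, LipAnnotation

# ---------------------------------------------------------------------------
# lip contours
# ---------------------------------------------------------------------------


@dataclass
class LipShapeParams:
    """Ground-truth parameters of a synthetic egret-lip outline.

    The body is a round-tipped lobe of ``body_length`` x ``body_width`` mm;
    each wing is a circular fan of radius ``wing_radius`` spanning
    ``wing_angular_extent`` degrees, its axis at ``body_wing_angle`` degrees
    from the body axis.  Serration is a sinusoidal radial modulation of the
    left wing's distal margin: ``r(t) = R + a*sin(2*pi*k*t)`` over the arc,
    giving exactly ``k = serration_count`` teeth of prominence
    ``a = serration_amplitude``.  ``jitter_sd`` adds Gaussian vertex noise
    (seeded) to emulate measurement error.
    """

    body_length: float = 12.0
    body_width: float = 4.0
    wing_radius: float = 15.0
    wing_angular_extent: float = 100.0
    body_wing_angle: float = 80.0
    serration_count: int = 25
    serration_amplitude: float = 0.6
    vertices_per_unit: float = 10.0
    jitter_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.body_length, self.body_width, self.wing_radius) <= 0:
            raise ValueError("all lengths must be positive")
        if not 0 < self.wing_angular_extent < 180:
            raise ValueError("wing_angular_extent must be in (0, 180)")
        if not 0 < self.body_wing_angle < 180:
            raise ValueError("body_wing_angle must be in (0, 180)")
        if self.serration_count < 0 or self.serration_count != int(self.serration_count):
            raise ValueError("serration_count must be a non-negative integer")
        if self.serration_amplitude < 0:
            raise ValueError("serration_amplitude must be >= 0")
        if self.serration_amplitude >= self.wing_radius:
            raise ValueError("serration_amplitude must be < wing_radius")
        if self.vertices_per_unit <= 0:
            raise ValueError("vertices_per_unit must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


#: Fraction of the body length at which the wing fans attach.
_WING_ATTACH = 0.15


def _rot(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s], [s, c]])


def _wing_arc(params: LipShapeParams, center: np.ndarray, axis_angle: float,
              serrated: bool) -> np.ndarray:
    """Distal-margin arc vertices of one wing fan, base-to-tip-to-base order."""
    R = params.wing_radius
    ext = math.radians(params.wing_angular_extent)
    arc_len = R * ext
    k = int(params.serration_count)
    npts = max(int(round(arc_len * params.vertices_per_unit)), 16)
    if serrated and k > 0:
        npts = max(npts, 8 * k)  # >= 8 vertices per tooth
    t = np.linspace(0.0, 1.0, npts)
    theta = axis_angle - ext / 2 + t * ext
    r = np.full(npts, R)
    if serrated and k > 0:
        r = R + params.serration_amplitude * np.sin(2 * np.pi * k * t)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _body_polygon(params: LipShapeParams) -> np.ndarray:
    """Round-tipped body lobe: base edge at y=0, tip at (0, -body_length)."""
    L, w = params.body_length, params.body_width
    r = w / 2
    cap_center_y = -L + r
    n_side = max(int(round((L - r) * params.vertices_per_unit)), 2)
    n_cap = max(int(round(math.pi * r * params.vertices_per_unit)), 8)
    n_cap += (n_cap + 1) % 2  # odd count so the exact tip (0, -L) is a vertex
    left = np.column_stack([np.full(n_side, -r), np.linspace(0, cap_center_y, n_side)])
    phi = np.linspace(math.pi, 2 * math.pi, n_cap)
    cap = np.column_stack([r * np.cos(phi), cap_center_y + r * np.sin(phi)])
    right = np.column_stack([np.full(n_side, r), np.linspace(cap_center_y, 0, n_side)])
    return np.vstack([left, cap[1:-1], right])


def generate_lip_contour(params: LipShapeParams) -> tuple[LipAnnotation, dict]:
    """Build a synthetic annotated lip; returns (annotation, truth).

    ``truth`` maps measurement names to the generating parameter values
    (body_length, body_width, wing_length, angle, serration_count,
    serration_amplitude).  The whole-lip contour is the simple CCW outline
    of the union of body and wing fans; the left-wing sub-contour keeps its
    own vertices with the serrated distal margin marked as a half-open
    vertex range.

    Raises
    ------
    GeometryError
        If the parameter combination yields a self-intersecting or
        disconnected outline.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    body_axis = np.array([0.0, -1.0])  # base (0,0) -> tip (0,-L)
    beta = params.body_wing_angle
    left_dir = _rot(-beta) @ body_axis
    right_dir = _rot(beta) @ body_axis
    wing_base = np.array([0.0, -_WING_ATTACH * params.body_length])

    left_arc0 = _wing_arc(params, wing_base, math.atan2(left_dir[1], left_dir[0]),
                          serrated=True)
    right_arc0 = _wing_arc(params, wing_base, math.atan2(right_dir[1], right_dir[0]),
                           serrated=False)
    body_v0 = _body_polygon(params)

    def assemble(left_arc, right_arc, body_v, noisy: bool):
        left_wing_v = np.vstack([wing_base, left_arc])
        right_wing_v = np.vstack([wing_base, right_arc])
        polys = []
        for name, v in (("body", body_v), ("left wing", left_wing_v),
                        ("right wing", right_wing_v)):
            poly = Polygon(v)
            if not poly.is_valid:
                raise GeometryError(
                    f"{name} outline self-intersects"
                    + ("" if noisy else " for these parameters")
                )
            polys.append(poly)
        lip = unary_union(polys)
        if lip.geom_type != "Polygon" or lip.interiors:
            raise GeometryError("lip outline is disconnected or has holes")
        return left_wing_v, np.asarray(lip.exterior.coords)[:-1]

    # the noise-free parametric shape must itself be valid
    left_wing_v, lip_v = assemble(left_arc0, right_arc0, body_v0, noisy=False)

    if params.jitter_sd > 0:
        # vertex noise occasionally crosses adjacent dense edges; redraw it
        for _ in range(20):
            try:
                left_wing_v, lip_v = assemble(
                    left_arc0 + rng.normal(0, params.jitter_sd, left_arc0.shape),
                    right_arc0 + rng.normal(0, params.jitter_sd, right_arc0.shape),
                    body_v0 + rng.normal(0, params.jitter_sd, body_v0.shape),
                    noisy=True,
                )
                break
            except GeometryError:
                continue
        else:
            raise GeometryError(
                "jittered outline remained self-intersecting after 20 redraws"
            )

    # left-wing contour: base vertex then the serrated arc.  Contour()
    # normalises orientation to CCW; remap the margin range if it reversed.
    wing_contour = Contour(left_wing_v, closed=True)
    n_wing = len(left_wing_v)
    if np.allclose(wing_contour.vertices[0], left_wing_v[0]) and np.allclose(
            wing_contour.vertices[1], left_wing_v[1]):
        margin = (1, n_wing)
    else:
        margin = (0, n_wing - 1)

    annotation = LipAnnotation(
        lip_contour=Contour(lip_v, closed=True),
        left_wing_contour=wing_contour,
        body_base=np.array([0.0, 0.0]),
        body_tip=np.array([0.0, -params.body_length]),
        body_width_segment=(
            np.array([-params.body_width / 2, -0.4 * params.body_length]),
            np.array([params.body_width / 2, -0.4 * params.body_length]),
        ),
        wing_base=wing_base,
        wing_tip=wing_base + params.wing_radius * left_dir,
        serrated_margin=margin,
    )
    truth = {
        "body_length": params.body_length,
        "body_width": params.body_width,
        "wing_length": params.wing_radius,
        "angle": params.body_wing_angle,
        "serration_count": 0 if params.serration_amplitude == 0
        else int(params.serration_count),
        "serration_amplitude": params.serration_amplitude,
    }
    return annotation, truth


# ---------------------------------------------------------------------------
# SSR genotypes
# ---------------------------------------------------------------------------

#: Per-population sample sizes of the eight-habitat survey regime.
DEFAULT_POP_SIZES = (9, 9, 9, 7, 10, 9, 5, 18)


def _default_pop_names(k: int) -> list[str]:
    letters = string.ascii_uppercase
    names = []
    for i in range(k):
        suffix = letters[i % 26] * (i // 26 + 1)
        names.append(f"Pop{suffix}")
    return names


@dataclass
class PopSimParams:
    """Simulation regime for diploid SSR genotype datasets.

    Per population and locus, allele frequencies are drawn from a symmetric
    Dirichlet with concentration ``freq_concentration`` (small values give
    divergent, skewed spectra).  Genotypes are then drawn either with
    within-population inbreeding ``f_is_per_pop`` or, when
    ``admixture_alpha`` is set, with individual admixture proportions
    ``q ~ Dirichlet(alpha, ..., alpha)`` over ``n_populations`` ancestral
    clusters — the two regimes are mutually exclusive.  Alleles are coded as
    dinucleotide-like fragment sizes (100, 102, 104, ...).
    """

    n_populations: int = 8
    n_individuals_per_pop: tuple[int, ...] | None = None
    n_loci: int = 21
    alleles_per_locus: int = 6
    freq_concentration: float = 1.0
    f_is_per_pop: tuple[float, ...] | None = None
    admixture_alpha: float | None = None
    clonal_founders: int | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def resolved_sizes(self) -> tuple[int, ...]:
        if self.n_individuals_per_pop is not None:
            return tuple(int(n) for n in self.n_individuals_per_pop)
        if self.n_populations == len(DEFAULT_POP_SIZES):
            return DEFAULT_POP_SIZES
        return (10,) * self.n_populations

    def resolved_f(self) -> tuple[float, ...]:
        if self.f_is_per_pop is None:
            return (0.0,) * self.n_populations
        f = tuple(float(x) for x in self.f_is_per_pop)
        if len(f) == 1:
            f = f * self.n_populations
        return f

    def validate(self) -> None:
        if self.n_populations < 1 or self.n_loci < 1 or self.alleles_per_locus < 1:
            raise ValueError("counts must be >= 1")
        sizes = self.resolved_sizes()
        if len(sizes) != self.n_populations or min(sizes) < 1:
            raise ValueError("need a sample size >= 1 for every population")
        if self.freq_concentration <= 0:
            raise ValueError("freq_concentration must be positive")
        f = self.resolved_f()
        if len(f) != self.n_populations:
            raise ValueError("f_is_per_pop length must match n_populations")
        if any(not -1 <= x <= 1 for x in f):
            raise ValueError("f_is values must lie in [-1, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.admixture_alpha is not None:
            if self.admixture_alpha <= 0:
                raise ValueError("admixture_alpha must be positive")
            if any(x != 0 for x in f):
                raise ValueError(
                    "admixture and nonzero F_IS are mutually exclusive regimes"
                )
        if self.clonal_founders is not None:
            if self.clonal_founders < 1:
                raise ValueError("clonal_founders must be >= 1")
            if self.clonal_founders > min(sizes):
                raise ValueError("clonal_founders cannot exceed the population size")


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset, for parameter recovery."""

    true_allele_freqs: np.ndarray  # (n_pops, n_loci, n_alleles)
    true_q: np.ndarray             # (n_individuals, n_pops), rows sum to 1
    true_f_is: np.ndarray          # (n_pops,)
    allele_sizes: np.ndarray       # (n_alleles,) fragment-size codes
    founders: np.ndarray | None = None  # per-individual founder id if clonal


def _genotype_distribution(p: np.ndarray, f: float) -> tuple[np.ndarray, np.ndarray]:
    """Unordered-genotype probabilities under inbreeding coefficient ``f``.

    P(ii) = p_i^2 + f p_i (1-p_i); P(ij) = 2 p_i p_j (1-f), i<j.
    Raises when ``f < 0`` would drive a homozygote probability negative —
    silently clamping would distort the regime being simulated.
    """
    A = len(p)
    pairs = [(i, i) for i in range(A)] + list(itertools.combinations(range(A), 2))
    probs = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        if i == j:
            probs[k] = p[i] ** 2 + f * p[i] * (1 - p[i])
        else:
            probs[k] = 2 * p[i] * p[j] * (1 - f)
    if probs.min() < -1e-12:
        raise ValueError(
            f"F = {f} makes a genotype probability negative for these frequencies"
        )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return np.asarray(pairs), probs


def _finalize(params: PopSimParams, calls: np.ndarray, pop_index: np.ndarray,
              rng: np.random.Generator) -> GenotypeDataset:
    sizes = params.resolved_sizes()
    pops = _default_pop_names(params.n_populations)
    individuals = []
    for p, n in enumerate(sizes):
        individuals += [f"{pops[p]}_{i + 1:03d}" for i in range(n)]
    if params.missing_rate > 0:
        drop = rng.random(calls.shape[:2]) < params.missing_rate
        calls[drop] = MISSING
    loci = [f"Hrad{j + 1:02d}" for j in range(params.n_loci)]
    return GenotypeDataset(
        populations=pops,
        pop_index=pop_index,
        individuals=individuals,
        loci=loci,
        calls=calls,
    )


def simulate_genotypes(params: PopSimParams,
                       freqs: np.ndarray | None = None
                       ) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate a multi-population diploid SSR dataset.

    Fully reproducible from ``params.seed``; child RNG streams are used for
    frequencies, genotypes and missingness so stages stay stable when one
    regime switch changes.  ``freqs`` (n_populations, n_loci, alleles) can
    pin the per-population allele frequencies instead of drawing them from
    the Dirichlet, for truth-controlled experiments.
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    rng_freq, rng_geno, rng_miss = (np.random.default_rng(s) for s in root.spawn(3))

    K, L, A = params.n_populations, params.n_loci, params.alleles_per_locus
    sizes = params.resolved_sizes()
    n_total = sum(sizes)
    pop_index = np.repeat(np.arange(K), sizes)
    allele_sizes = 100 + 2 * np.arange(A)

    if freqs is not None:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (K, L, A):
            raise ValueError(f"freqs must have shape {(K, L, A)}")
        if not np.allclose(freqs.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("freqs must sum to 1 per population and locus")
    else:
        freqs = rng_freq.dirichlet(np.full(A, params.freq_concentration), size=(K, L))
    f_is = np.asarray(params.resolved_f())

    calls = np.empty((n_total, L, 2), dtype=np.int64)
    if params.admixture_alpha is not None:
        q = rng_geno.dirichlet(np.full(K, params.admixture_alpha), size=n_total)
        # each allele copy: pick a source cluster by q, then an allele from it
        for l in range(L):
            u = rng_geno.random((n_total, 2, 1))
            z = (u > np.cumsum(q, axis=1)[:, None, :]).sum(axis=2)
            cum = np.cumsum(freqs[:, l, :], axis=1)
            a_idx = (rng_geno.random((n_total, 2, 1)) > cum[z]).sum(axis=2)
            calls[:, l, :] = allele_sizes[a_idx]
    else:
        q = np.zeros((n_total, K))
        q[np.arange(n_total), pop_index] = 1.0
        row = 0
        for p, n in enumerate(sizes):
            for l in range(L):
                pairs, probs = _genotype_distribution(freqs[p, l], f_is[p])
                pick = rng_geno.choice(len(pairs), size=n, p=probs)
                calls[row:row + n, l, :] = allele_sizes[pairs[pick]]
            row += n

    dataset = _finalize(params, calls, pop_index, rng_miss)
    truth = TruthRecord(
        true_allele_freqs=freqs,
        true_q=q,
        true_f_is=f_is,
        allele_sizes=allele_sizes,
    )
    return dataset, truth


def simulate_clonal_population(params: PopSimParams) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate bulb-propagated (clonal) populations.

    Per population, ``clonal_founders`` distinct multilocus genotypes are
    drawn at Hardy–Weinberg proportions and the sample is filled by copying
    founders uniformly at random.  Heterozygous founders then produce an
    observed-heterozygosity excess (negative fixation index), the signature
    of vegetative propagation after a bottleneck.
    """
    params.validate()
    if params.clonal_founders is None:
        raise ValueError("clonal_founders must be set for a clonal simulation")
    root = np.random.SeedSequence(params.seed)
    rng_freq, rng_geno, rng_miss = (np.random.default_rng(s) for s in root.spawn(3))

    K, L, A = params.n_populations, params.n_loci, params.alleles_per_locus
    nf = params.clonal_founders
    sizes = params.resolved_sizes()
    n_total = sum(sizes)
    pop_index = np.repeat(np.arange(K), sizes)
    allele_sizes = 100 + 2 * np.arange(A)

    freqs = rng_freq.dirichlet(np.full(A, params.freq_concentration), size=(K, L))

    calls = np.empty((n_total, L, 2), dtype=np.int64)
    founders = np.empty(n_total, dtype=np.intp)
    row = 0
    for p, n in enumerate(sizes):
        for _ in range(1000):
            fg = np.empty((nf, L, 2), dtype=np.int64)
            for l in range(L):
                pairs, probs = _genotype_distribution(freqs[p, l], 0.0)
                pick = rng_geno.choice(len(pairs), size=nf, p=probs)
                fg[:, l, :] = allele_sizes[pairs[pick]]
            if len({tuple(g.ravel()) for g in fg}) == nf:
                break
        else:
            raise RuntimeError("could not draw distinct founder genotypes")
        assign = rng_geno.integers(0, nf, size=n)
        assign[:min(nf, n)] = np.arange(min(nf, n))  # every founder represented
        calls[row:row + n] = fg[assign]
        founders[row:row + n] = assign
        row += n

    dataset = _finalize(params, calls, pop_index, rng_miss)
    q = np.zeros((n_total, K))
    q[np.arange(n_total), pop_index] = 1.0
    truth = TruthRecord(
        true_allele_freqs=freqs,
        true_q=q,
        true_f_is=np.zeros(K),
        allele_sizes=allele_sizes,
        founders=founders,
    )
    return dataset, truth
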