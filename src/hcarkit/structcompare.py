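"""Calpha superposition RMSD and the paired-t comparison of RMSD sets.

The structural question downstream of the sequence analysis is whether a
set of receptor models sits closer to one reference structure than to
another.  Each model is rigidly superposed on the reference over a stated
residue range using the Kabsch algorithm (SVD-based least squares with the
proper-rotation correction), yielding an RMSD in angstroms; the two RMSD
vectors, paired by model, are then compared with a classical two-tailed
paired t-test.

Pairing is by residue-number intersection and *missing residues inside the
requested range are an error*, not silently dropped — the published
comparisons use fixed ranges (8-302, 17-300) precisely so that n is
identical across models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats


class GeometryError(ValueError):
    """Too few atoms or degenerate (collinear) geometry."""


class FormatError(ValueError):
    """Malformed PDB ATOM records."""


class CoverageError(ValueError):
    """A model does not cover the requested residue range."""


@dataclass(frozen=True)
class CoordSet:
    """Ordered Calpha coordinates keyed by residue number.

    ``residue_numbers`` strictly increasing; ``coords`` is (n, 3) in
    angstroms.
    """

    model_id: str
    residue_numbers: tuple[int, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.residue_numbers), 3):
            raise GeometryError("coords must be (n_residues, 3)")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("coordinates must be finite")
        if any(
            b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])
        ):
            raise FormatError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def restrict(self, start: int, end: int) -> "CoordSet":
        """Sub-set to residues in [start, end]; all must be present."""
        present = set(self.residue_numbers)
        missing = [r for r in range(start, end + 1) if r not in present]
        if missing:
            raise CoverageError(
                f"model {self.model_id!r} is missing residues "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''} "
                f"in range {start}-{end}"
            )
        keep = [
            i for i, r in enumerate(self.residue_numbers) if start <= r <= end
        ]
        return CoordSet(
            model_id=self.model_id,
            residue_numbers=tuple(self.residue_numbers[i] for i in keep),
            coords=self.coords[keep],
        )


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform (mobile -> target) and the resulting RMSD."""

    rotation: np.ndarray  # (3,3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int
    range_used: tuple[int, int]


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t-test on per-model RMSD differences."""

    n: int
    mean_diff: float
    sd_diff: float
    t_statistic: float
    df: int
    p_value: float
    zero_variance: bool = False


# -- minimal PDB Calpha extraction ---------------------------------------
# Hand-parsed fixed-column ATOM records: the error semantics needed here
# (duplicate CA without altloc is a format error; only altloc 'A' or blank
# is read) are resolved silently by the general-purpose parsers.


def read_ca_coords(
    path: str | Path,
    chain: str = "A",
    residue_range: tuple[int, int] | None = None,
) -> CoordSet:
    """Extract one Calpha per residue from PDB ATOM records.

    Only altloc ' ' or 'A' atoms are considered.  A second Calpha for the
    same residue without a distinguishing altloc is a format error.
    """
    residues: dict[int, tuple[float, float, float]] = {}
    chains_seen = set()
    for line in Path(path).read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        name = line[12:16].strip()
        if name != "CA":
            continue
        chains_seen.add(line[21])
        if line[21] != chain:
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        resnum = int(line[22:26])
        if residue_range and not (residue_range[0] <= resnum <= residue_range[1]):
            continue
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        if resnum in residues:
            if altloc == " ":
                raise FormatError(
                    f"duplicate Calpha for residue {resnum} without altloc"
                )
            continue  # altloc A after blank: keep the first
        residues[resnum] = xyz
    if not residues:
        if chain not in chains_seen:
            raise LookupError(
                f"chain {chain!r} not found (saw {sorted(chains_seen)})"
            )
        raise FormatError(f"no Calpha atoms read from {path}")
    numbers = tuple(sorted(residues))
    coords = np.array([residues[r] for r in numbers], dtype=float)
    return CoordSet(
        model_id=Path(path).stem, residue_numbers=numbers, coords=coords
    )


def write_ca_pdb(coord_set: CoordSet, path: str | Path, chain: str = "A") -> None:
    """Write a CoordSet as a minimal Calpha-only PDB file."""
    lines = []
    for serial, (resnum, (x, y, z)) in enumerate(
        zip(coord_set.residue_numbers, coord_set.coords), start=1
    ):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# -- superposition -------------------------------------------------------


def kabsch_superpose(mobile: CoordSet, target: CoordSet) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of mobile onto target.

    Atoms are paired by residue-number intersection (order preserved).
    The rotation is constrained to be proper (det = +1): reflections are
    corrected by flipping the smallest singular vector, the standard
    Kabsch fix.
    """
    common = sorted(set(mobile.residue_numbers) & set(target.residue_numbers))
    if len(common) < 3:
        raise GeometryError(
            f"need >= 3 shared residues, have {len(common)}"
        )
    idx_m = {r: i for i, r in enumerate(mobile.residue_numbers)}
    idx_t = {r: i for i, r in enumerate(target.residue_numbers)}
    P = mobile.coords[[idx_m[r] for r in common]]  # mobile
    Q = target.coords[[idx_t[r] for r in common]]  # target
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) mobile geometry")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff * diff).sum() / len(common)))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_atoms=len(common),
        range_used=(common[0], common[-1]),
    )


def rmsd_over_range(
    model_a: CoordSet, model_b: CoordSet, residue_range: tuple[int, int]
) -> SuperpositionResult:
    """Kabsch superposition restricted to a residue interval.

    Both models must cover every residue in the interval; missing residues
    raise :class:`CoverageError` listing them.
    """
    start, end = residue_range
    result = kabsch_superpose(
        model_a.restrict(start, end), model_b.restrict(start, end)
    )
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_atoms=result.n_atoms,
        range_used=(start, end),
    )


# -- paired t ------------------------------------------------------------


def paired_ttest(
    rmsd_to_a: Sequence[float], rmsd_to_b: Sequence[float]
) -> PairedTestResult:
    """Two-tailed paired t-test on per-model RMSD differences.

    t = mean(d) / (sd(d)/sqrt(n)) with d_i = a_i - b_i and the unbiased
    (n-1) standard deviation; p from the Student t distribution with
    df = n-1.  Zero-variance differences with nonzero mean are reported
    with t = +/-inf, p = 0 and the ``zero_variance`` flag set.
    """
    a = np.asarray(rmsd_to_a, dtype=float)
    b = np.asarray(rmsd_to_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(
                n=n, mean_diff=0.0, sd_diff=0.0, t_statistic=0.0,
                df=df, p_value=1.0, zero_variance=True,
            )
        return PairedTestResult(
            n=n, mean_diff=mean, sd_diff=0.0,
            t_statistic=math.copysign(math.inf, mean),
            df=df, p_value=0.0, zero_variance=True,
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(
        n=n, mean_diff=mean, sd_diff=sd, t_statistic=t, df=df, p_value=min(p, 1.0)
    )
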