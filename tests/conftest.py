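"""Shared fixtures and independent brute-force oracles.

The oracle functions are deliberately naive (python loops, BFS) and
share no code with the package's vectorized implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from fltseg import CohortSpec, generate_cohort


def oracle_voi_stats(pet: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, float]:
    """Scalar-loop mean / population SD / min / max over masked voxels."""
    vals = []
    for idx in np.ndindex(pet.shape):
        if mask[idx]:
            vals.append(float(pet[idx]))
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    return mean, var**0.5, min(vals), max(vals)


def oracle_component_count(fg: np.ndarray, connectivity: int = 26) -> int:
    """Flood-fill (BFS) connected-component count of a binary 3D field."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(fg, dtype=bool)
    count = 0
    for start in np.ndindex(fg.shape):
        if not fg[start] or seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= nb[a] < fg.shape[a] for a in range(3)):
                    if fg[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
    return count


def oracle_mean_of_ratios(lesion_mins, refs_by_patient) -> float:
    """Explicit double-loop lesion-minimum-to-reference ratio average."""
    total, n = 0.0, 0
    for pid, mins in lesion_mins.items():
        for m in mins:
            total += m / refs_by_patient[pid]
            n += 1
    return total / n


def oracle_sphere_count(center, diameter, shape, spacing, origin=(0.0, 0.0, 0.0)) -> int:
    """Count voxel centers within diameter/2 of center, by scalar loop."""
    r2 = (diameter / 2.0) ** 2
    count = 0
    for idx in np.ndindex(tuple(shape)):
        d2 = sum(
            (origin[a] + idx[a] * spacing[a] - center[a]) ** 2 for a in range(3)
        )
        if d2 <= r2:
            count += 1
    return count


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient noisy volumetric cohort, generated once per session."""
    spec = CohortSpec(n_patients=4, seed=11)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A 2-patient noise-free cohort for exact-value checks."""
    spec = CohortSpec(n_patients=2, within_voi_cv=0.0, seed=5)
    return spec, generate_cohort(spec)
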