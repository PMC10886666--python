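"""Per-patient instance bags shared by the MIL classifier and MISL regressor."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLUSTERS = ("C1", "C2", "C3")


@dataclass
class InstanceBag:
    """All feature vectors (instances) belonging to one patient.

    ``instances`` is an (n, m) matrix — n patches, m features; bags may have
    different n. ``label`` carries a binary relapse-within-horizon label for
    classification; ``time_days``/``event`` carry relapse-free-survival data
    for survival learning. Either may be absent.
    """

    patient_id: str
    instances: np.ndarray
    cluster_labels: list[str] = field(default_factory=list)
    label: int | None = None
    time_days: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=np.float64)
        if self.instances.ndim != 2 or self.instances.shape[0] < 1:
            raise ValueError("instances must be a non-empty (n, m) matrix")
        if self.cluster_labels and len(self.cluster_labels) != self.instances.shape[0]:
            raise ValueError("cluster_labels length must match instance count")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def n_features(self) -> int:
        return self.instances.shape[1]

    @property
    def survival(self) -> tuple[float, int] | None:
        if self.time_days is None or self.event is None:
            return None
        return (self.time_days, self.event)


def stack_bags(bags: list[InstanceBag]) -> tuple[np.ndarray, np.ndarray]:
    """Stack bag instances into one matrix plus a bag-index vector."""
    X = np.vstack([b.instances for b in bags])
    bag_ids = np.concatenate(
        [np.full(b.n_instances, i, dtype=np.int64) for i, b in enumerate(bags)]
    )
    return X, bag_ids
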