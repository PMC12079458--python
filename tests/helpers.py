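import numpy as np

from aggrekin.segment import AggregateCluster


def cluster_from_truth(table, truth, aggregate_id=1):
    """Build an AggregateCluster from the ground-truth sidecar."""
    rows = np.flatnonzero(truth.aggregate_ids == aggregate_id)
    times = table.times_s[rows]
    return AggregateCluster(aggregate_id, rows, float(times.min()), float(times.max()))
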