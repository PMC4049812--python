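"""Build horizon-N datasets from a t=0 labeled instance stream.

The horizon-N model targets seizure onset N to N+5 minutes ahead: the
N minutes before onset are removed and the 5 minutes before that are
relabeled pre-ictal.  On the canonical one-hour layout this removes
12*N instances and changes the labels of 12*min(N, 5) instances.
"""

import numpy as np

from asppr import (FeatureMatrix, instance_times, label_instances,
                   relabel_for_horizon)

seizures = [(1800.0, 1980.0)]
t = instance_times(3600.0)
labels = label_instances(t, seizures)
matrix = FeatureMatrix(values=np.zeros((len(t), 1)), timestamps=t,
                       labels=labels, column_names=["placeholder"])

print(f"t=0 dataset: {matrix.n_instances} instances, "
      f"{np.sum(labels == 'pre-ictal')} pre-ictal")
print(f"{'N':>3} {'removed':>8} {'relabeled':>10} {'instances':>10} {'pre':>5}")
for n in (0, 1, 2, 5, 10, 20):
    hd = relabel_for_horizon(matrix, n, seizures)
    pre = int(np.sum(hd.matrix.labels == "pre-ictal"))
    print(f"{n:>3} {hd.removed_count:>8} {hd.relabeled_count:>10} "
          f"{hd.matrix.n_instances:>10} {pre:>5}")
# The pre-ictal class stays at 60 instances for every horizon (the
# 5-minute window just moves earlier); the dataset shrinks by 12 ticks
# per horizon minute.
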