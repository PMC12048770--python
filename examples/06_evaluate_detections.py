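"""Average precision from first principles.

Two hand-checkable cases: a perfect detector scores AP = 1; a false
positive ranked above the only true positive halves the AP, because the
precision envelope over recall integrates to 0.5.
"""

import numpy as np

from vegdet.evaluation import average_precision, iou

print("perfect detector, 3 detections / 3 GT:",
      average_precision([True, True, True], [0.9, 0.8, 0.7], n_gt=3))
print("FP at conf 0.9, TP at conf 0.8, 1 GT: ",
      average_precision([False, True], [0.9, 0.8], n_gt=1))
print("IoU of (0,0,2,2) vs (1,1,3,3):        ",
      round(iou(np.array([0, 0, 2, 2]), np.array([1, 1, 3, 3])), 6), "(= 1/7)")
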