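"""Layer-wise relevance propagation on toy networks.

Shows the proportional-split rule, exact conservation with epsilon = 0, and
the classic failure of weight-magnitude (WM) scores that motivates LRP: the
input with the largest weights is not the one driving the output.
"""

from deeplrp import LRPConfig, forward_trace, relevance_from_output, wm_scores
from deeplrp.synthetic import make_toy_network

eps0 = LRPConfig(epsilon=0.0)

# two inputs with weights [1, 3] into one output: relevance splits 1:3
net, x = make_toy_network("two_input")
rvec = relevance_from_output(net, forward_trace(net, x), 0, eps0)
print("two_input: output score", rvec.start_relevance[0],
      "-> input relevances", rvec.input_relevances()[0])

# a 3-input ReLU net where WM and LRP disagree
net, x = make_toy_network("fig3_style")
trace = forward_trace(net, x)
rvec = relevance_from_output(net, trace, 0, eps0)
lrp = rvec.input_relevances()[0]
wm = wm_scores(net, 0, "mean_abs_outgoing").scores
print(f"fig3_style: input {x.tolist()}, output score {trace.z[2][0, 0]:.3f}")
print(f"  WM scores       : {wm.round(3)}  (argmax input {wm.argmax() + 1})")
print(f"  LRP relevances  : {lrp.round(3)}  (argmax input {lrp.argmax() + 1})")
print(f"  conservation    : sum of input relevances = {lrp.sum():.3f}")
# WM picks input 2 (big weights, near-zero activation); LRP picks input 3,
# whose activation actually reaches the output, and the relevances sum back
# to the output score exactly.
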