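import numpy as np


def sigmoid(u):
    """Logistic function 1/(1+exp(-u)), stable for |u| up to ~700."""
    u = np.clip(u, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(-u))
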