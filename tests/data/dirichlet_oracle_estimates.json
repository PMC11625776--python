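{"beta1": [0.3228913476, -0.5553008417], "beta2": [-0.7357758241, 0.6867450290], "phi": 3.5151155827, "loglik": 98.2678914332}
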