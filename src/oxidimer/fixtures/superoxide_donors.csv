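phase,compound,forms
gas,3HAAi,D2|D3|D4|D7|D8|D3p
heptane,3HAAi,D1|D2|D3|D4|D5|D6|D7|D8|D9|D10|D1p|D3p
water,3HAAi,
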