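set_id,m_tau_r,m_beta,m_vmod_m,m_vmod_s
1,1.33,0.76,1.76,0.93
2,0.58,0.72,1.62,0.92
3,0.82,0.74,1.57,0.95
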