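# Accelerated liquid nitrogen: diatomic mode-mass matrix with a 100-fold
# vibrational and 4-fold rotational mass. Units are stated per key.
system:     {kind: n2_liquid, n_molecules: 64}     # box scaled to the
                                                   # 512-per-(32 Å)³ density
forcefield: {kind: n2, cutoff: 7.0}                # Å
mass_model: {kind: diatomic, m_trans: 14.007,      # u
             m_rot: 56.028, m_vib: 1400.7}
integrator: {dt_fs: 4.0, W: 1792.9}                # fs; cell mass in u
ensemble:   {temperature: 180.0,                   # K (≈90 K after
             pressure_gpa: 0.0001,                 #    equipartition)
             uniform_scaling: true}
io:         {seed: 1, stride: 2}
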