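# Imaginary anomalous scattering coefficients f'' (electrons) at the two
# wavelengths used in the study: Re L1-edge-optimised synchrotron setting
# and laboratory Cu K-alpha.
element,wavelength,f_double_prime
Re,0.9760,12.1
Re,1.5418,5.9
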