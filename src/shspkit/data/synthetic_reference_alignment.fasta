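>bacterial_class_A_like synthetic class template
VNEEKDCVEFFVQIQKPTYVVQSTINIAISLIRQFLRISAFRIFVYAQQQGYVPPSRQFDFWPLPTHSMSSTQNATGYMMGGDFDTRNESQVAQKSLAGFIVMSSGMNCPKPKNKPEASFSSCRGHNCGWLKVAELYMIYPNNFHGMPQLAIEKTDNRSE
>class_B_plant_like synthetic class template
DQSEKDENRMDVTGRKTNEAVQIMENIQPSHTFGFNRISQDANFVVPQAQGYVPPSIQFTFDPLPQHSHSYTNLCGGYKWVMFTEDRNESQWAPKSSPGKRVMQFTFNYPKLLRSKEARMSFVRDHNCSWLKVDEYYMIQPNNFHGMPDLAIEKTNQSSE
>cyanobacterial_like synthetic class template
VEWERDINRLDVTENKTMETVQWTCNISGVIIRLVMPISQFCIFVYYHAQMYVPPSEQFHFHPLPTHSMSSTFVLTTIMMTMFFEDMNEMQLAEKSSPGKWEMQEGHNKPKPFRVHEIVDEFMRPHNCIWPKVDESWMINCEKFHGMPEIAVALKEDNSR
>cyanophage_like synthetic class template
VQEEMTLNRMDVKRQKTSETVQIKETQFCSLSRQFLRISQFIIFVRAQDQGYVPPSPPYNIVPLHQQELSSEFGRGGYMSGGEFEVRNEFQLAPKSLAGFSVMTEGMKYSTFMRVRENVDWEDRPHLCIWNKVDPDWQINPCNFHGMPKLAVAEKDNKTE
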