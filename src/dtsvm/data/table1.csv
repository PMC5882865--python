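label,species_name,family,order,quantity,range_suspect,mass_mean,mass_std,mass_min,mass_max,wingbeat_frequency_mean,wingbeat_frequency_std,wingbeat_frequency_min,wingbeat_frequency_max,length_to_width_ratio_mean,length_to_width_ratio_std,length_to_width_ratio_min,length_to_width_ratio_max,body_length_mean,body_length_std,body_length_min,body_length_max
A,Eriopyga grandis,Noctuidae,Lepidoptera,473,0,62.98,2.41,55.7,69.3,45.15,3.57,36,57,3.52,0.91,2,7,11.22,1.12,8,14
B,Agrotis tokionis,Noctuidae,Lepidoptera,382,0,266.45,4.97,252.2,280.9,58.30,5.85,38,75,3.88,0.51,2.7,5.8,27.18,1.35,24,31
C,Agrotis c-nigrum,Noctuidae,Lepidoptera,43,0,215.01,5.38,203.2,224.7,46.44,5.41,36,57,4.53,0.57,3.3,5.4,24.47,1.47,21,27
D,Agrotis praecox,Noctuidae,Lepidoptera,78,0,233.83,7.86,209.9,253.3,42.47,5.38,31,58,4.00,0.46,3.2,5.2,22.70,1.83,18,27
E,Spodoptera litura,Noctuidae,Lepidoptera,129,1,143.97,2.59,37.1,152.0,56.88,3.98,45,66,4.93,0.80,3,7,18.64,1.35,15,21
F,Heliothis dipsacea,Noctuidae,Lepidoptera,84,0,107.37,2.72,100.6,114.4,44.31,3.48,37,56,4.44,0.84,3.2,8.0,15.51,1.26,13,19
G,Speiredonia retorta,Noctuidae,Lepidoptera,32,0,326.96,10.63,306.1,355.6,24.75,3.02,18,30,6.72,1.32,4.4,9.3,25.47,1.88,22,29
H,Dermaleipa juno,Noctuidae,Lepidoptera,61,0,472.79,13.09,444.5,511.8,28.34,2.48,22,34,3.71,0.30,3.0,4.5,42.56,1.47,39,45
I,Acronicta rumicis,Noctuidae,Lepidoptera,58,0,85.35,4.18,76.7,91.8,48.76,3.92,41,57,4.99,0.56,4.0,7.5,14.72,0.87,12,16
J,Calospilos suspecta,Geometridae,Lepidoptera,147,0,117.43,3.04,110.9,127.8,25.97,2.84,19,33,9.31,0.87,5.6,11,18.78,1.39,16,22
K,Spilarctia subcarnea,Arctiidae,Lepidoptera,296,0,94.60,3.54,85.6,104.7,47.78,5.10,33,64,4.30,0.82,2.8,8.9,18.10,1.11,15,21
L,Spilosoma niveus,Arctiidae,Lepidoptera,48,0,188.20,4.35,178.3,198.3,52.94,4.19,42,66,5.07,0.61,4.0,7.2,27.38,1.20,24,29
M,Amsacta lactinea,Arctiidae,Lepidoptera,27,0,218.71,17.49,169.0,242.7,57.00,2.95,50,63,4.76,0.51,4,6,24.81,1.18,22,28
N,Rhyparioides amurensis,Arctiidae,Lepidoptera,144,0,134.30,3.68,125.0,145.2,46.27,2.95,39,53,4.49,0.63,3.4,6.7,16.77,1.20,14,20
O,Clanis bilineata,Sphingidae,Lepidoptera,53,0,459.28,23.32,416.0,519.0,36.51,1.76,31,40,3.56,0.62,2.6,5.8,42.98,2.18,38,47
P,Psilogramma menephron,Sphingidae,Lepidoptera,29,0,326.18,5.82,311.4,337.5,41.48,1.62,38,45,5.43,0.49,4.5,6.7,46.00,1.87,41,48
Q,Ampelophaga rubiginosa,Sphingidae,Lepidoptera,41,0,381.99,8.60,365.2,412.6,48.46,1.95,44,54,5.10,0.46,4.4,6.9,46.85,1.37,43,49
R,Callambulyx tartarunovii,Sphingidae,Lepidoptera,35,0,304.78,13.68,277.0,332.7,45.60,1.93,42,50,2.26,0.17,2.0,2.6,31.29,1.34,28,34
S,Macroglossum stellatarum,Sphingidae,Lepidoptera,84,0,227.29,7.00,211.7,244.1,233.40,19.60,182,289,2.25,0.19,1.8,2.9,27.77,1.47,24,31
T,Loxostege sticticalis,Pyralididae,Lepidoptera,892,0,67.37,2.39,59.9,75.3,47.21,4.35,33,60,7.11,2.19,3.0,11,8.71,0.66,6,11
U,Spoladea recurvalis,Pyralididae,Lepidoptera,1574,0,14.52,2.79,5.2,23.8,42.28,4.88,28,59,6.14,0.71,2.5,8.0,6.19,0.58,4,8
V,Pantala flavescens,Libellulidae,Odonata,768,0,182.77,13.07,138.8,223.0,137.48,5.70,120,155,5.40,0.37,4.4,6.5,66.64,2.26,60,74
W,Enallagma cyathigerum,Coenagriidae,Odonata,54,0,125.15,2.05,121.1,130.1,82.76,3.87,74,92,9.04,1.07,7.3,13,47.19,1.91,42,53
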