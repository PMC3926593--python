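date,rice_color,condition,referenced_cm,estimated_cm,relative_error_pct
2012-07-01,green,normal,77.0,77.0,0.00
2012-07-02,green,normal,77.0,78.3,1.65
2012-07-03,green,normal,77.0,79.5,3.30
2012-07-04,green,normal,78.0,79.5,1.98
2012-07-05,green,normal,78.0,79.5,1.98
2012-07-06,green,normal,79.0,80.81,2.30
2012-07-07,green,normal,80.0,84.6,5.78
2012-07-08,green,normal,81.0,84.6,4.48
2012-07-09,green,normal,81.0,83.4,2.91
2012-07-10,green,normal,82.0,80.8,1.45
2012-07-11,green,darkness,84.0,87.2,3.77
2012-07-12,green,normal,85.0,85.9,1.06
2012-07-13,green,normal,87.0,85.9,1.27
2012-07-14,green,normal,85.0,84.6,0.44
2012-07-15,green,normal,87.0,88.4,1.66
2012-07-16,green,normal,88.0,87.2,0.94
2012-07-17,green,normal,89.0,91.0,2.23
2012-07-18,green,darkness,99.0,106.2,7.31
2012-07-19,green,drizzle,108.0,116.4,7.78
2012-07-20,golden,normal,116.0,112.6,2.94
2012-07-21,golden,normal,119.0,118.9,0.04
2012-07-22,golden,normal,119.0,120.2,1.03
2012-07-23,golden,normal,117.0,117.7,0.58
2012-07-24,golden,darkness,117.0,117.7,0.58
2012-07-25,golden,rainfall,117.0,159.6,36.43
2012-07-26,golden,normal,119.0,121.5,2.09
2012-07-27,golden,darkness,117.0,115.1,1.59
2012-07-28,golden,normal,115.0,113.9,0.99
2012-07-29,golden,normal,115.0,115.1,0.12
2012-07-30,golden,darkness,111.0,111.3,0.29
2012-07-31,golden,normal,112.0,113.9,1.66
2012-08-01,golden,normal,112.0,113.9,1.66
2012-08-02,golden,darkness,110.0,113.9,3.51
2012-08-03,golden,normal,109.0,115.1,5.63
2012-08-04,golden,brightness,108.0,108.8,0.72
2012-08-05,golden,brightness,108.0,112.6,4.25
2012-08-06,golden,darkness,108.0,112.6,4.25
2012-08-07,golden,normal,111.0,115.1,3.73
2012-08-08,golden,darkness,110.0,115.1,4.67
2012-08-09,golden,darkness,110.0,112.6,2.36
2012-08-10,golden,normal,109.0,112.6,3.30
2012-08-11,golden,normal,108.0,110.1,1.90
2012-08-12,golden,normal,110.0,112.6,2.36
2012-08-13,golden,normal,107.0,111.3,4.04
2012-08-14,golden,normal,105.0,111.3,6.02
2012-08-15,golden,normal,106.0,110.1,3.82
2012-08-16,golden,brightness,106.0,110.1,3.82
2012-08-17,golden,normal,100.0,103.7,3.69
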