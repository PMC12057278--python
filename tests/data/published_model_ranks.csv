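response,model,ll,n,k,aicc,delta,weight
date,age+sex+year+age:sex,-474.2,142,6,961.1,0.0,0.35
date,age+sex+age:sex,-475.5,142,5,961.4,0.28,0.30
date,age+sex,-477.2,142,4,962.7,1.61,0.16
time,age,-727.1,141,3,1460.3,0.0,0.29
time,age+year,-726.1,141,4,1460.4,0.14,0.27
time,age+year+sex,-725.5,141,5,1461.5,1.14,0.16
time,age+sex,-726.7,141,4,1461.8,1.47,0.14
speed,tailwind+year,-99.1,27,4,208.1,0.0,0.33
speed,tailwind,-98.7,27,3,209.4,1.35,0.17
speed,age+tailwind,-99.2,27,4,209.6,1.50,0.16
pace,age+sex+year+latitude,-119.6,31,7,258.0,0.0,0.28
pace,age+sex+year+latitude+departure_date,-118.1,31,8,258.7,0.74,0.19
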